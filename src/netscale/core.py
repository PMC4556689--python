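"""Network data model, config I/O and the mean-field working point.

Conventions used throughout the package:

* times and delays are in ms, potentials in mV (binary networks use a
  dimensionless drive scale), firing rates in spikes/s at all interfaces;
* the dimensionless population activity is ``nu`` — the mean of the binary
  state variable, or ``tau_m * r`` (with ``tau_m`` in seconds) for spiking
  populations;
* ``K[a, b]`` is the in-degree of a neuron in population ``a`` for synapses
  from population ``b``; ``J[a, b]`` the corresponding synaptic weight;
* angular frequencies are in rad/ms wherever spectra appear.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "NeuronParams",
    "Drive",
    "NetworkSpec",
    "WorkingPoint",
    "EffectiveConnectivity",
    "CovarianceSet",
    "PoleSet",
    "SpecValidationError",
    "load_network_spec",
    "save_network_spec",
    "working_point_equations",
]

SCHEMA_TAG = "netscale-spec"
SCHEMA_VERSION = "v1"


class SpecValidationError(ValueError):
    """A network specification violates the documented schema."""


def _round_half_up(x):
    """Round to nearest integer with ties away from zero (documented rule
    for converting connection probabilities to in-degrees)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class NeuronParams:
    """Single-neuron parameters for one population.

    ``model`` is ``"binary"`` (stochastic two-state neuron with Heaviside
    gain, update time constant ``tau_m``) or ``"lif"`` (leaky
    integrate-and-fire with exponential current synapses).
    """

    model: str
    tau_m: float
    theta: float
    tau_s: float = 0.0
    tau_ref: float = 0.0
    V_r: float = 0.0

    def validate(self) -> None:
        if self.model not in ("binary", "lif"):
            raise SpecValidationError(f"neuron.model must be 'binary' or 'lif', got {self.model!r}")
        if self.tau_m <= 0:
            raise SpecValidationError("neuron.tau_m must be > 0")
        if self.tau_ref < 0:
            raise SpecValidationError("neuron.tau_ref must be >= 0")
        if self.model == "lif":
            if self.tau_s <= 0:
                raise SpecValidationError("neuron.tau_s must be > 0 for lif")
            if not self.theta > self.V_r:
                raise SpecValidationError("neuron.theta must exceed V_r for lif")


@dataclass
class Drive:
    """External drive of one population.

    Kinds:

    * ``gaussian`` — independent Gaussian input with mean ``mu_ext`` and
      standard deviation ``sigma_ext`` (current for LIF, dimensionless for
      binary neurons);
    * ``poisson_balanced`` — excitatory and inhibitory Poisson spike trains
      with rates ``rate_e``, ``rate_i`` (spikes/s), weights ``J_ext`` and
      ``-g_ext * J_ext`` (mV), plus a DC current ``I_dc``;
    * ``dc`` — constant current ``I_dc`` only.
    """

    kind: str
    mu_ext: float = 0.0
    sigma_ext: float = 0.0
    rate_e: float = 0.0
    rate_i: float = 0.0
    J_ext: float = 0.1
    g_ext: float = 1.0
    I_dc: float = 0.0

    def validate(self) -> None:
        if self.kind not in ("gaussian", "poisson_balanced", "dc"):
            raise SpecValidationError(f"unknown drive kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma_ext < 0:
            raise SpecValidationError("drive.sigma_ext must be >= 0")
        if self.kind == "poisson_balanced" and (self.rate_e < 0 or self.rate_i < 0):
            raise SpecValidationError("Poisson drive rates must be >= 0")

    def moments(self, tau_m: float) -> tuple[float, float]:
        """Mean and variance of the summed external input.

        For Poisson drive the diffusion approximation gives
        ``mu = tau_m * J_ext * (rate_e - g_ext * rate_i) + I_dc`` and
        ``sigma^2 = tau_m * J_ext**2 * (rate_e + g_ext**2 * rate_i)`` with
        ``tau_m`` passed in ms and converted to seconds internally.
        """
        if self.kind == "gaussian":
            return self.mu_ext, self.sigma_ext**2
        if self.kind == "dc":
            return self.I_dc, 0.0
        tm = tau_m * 1e-3
        mu = tm * self.J_ext * (self.rate_e - self.g_ext * self.rate_i) + self.I_dc
        var = tm * self.J_ext**2 * (self.rate_e + self.g_ext**2 * self.rate_i)
        return mu, var


@dataclass
class NetworkSpec:
    """Full parameterization of a multi-population recurrent network."""

    populations: list[str]
    N: np.ndarray
    K: np.ndarray
    J: np.ndarray
    d: np.ndarray
    neuron: list[NeuronParams]
    drive: list[Drive]

    def __post_init__(self):
        self.N = np.asarray(self.N, dtype=int)
        self.K = np.asarray(self.K, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.validate()

    # -- basic structure ---------------------------------------------------
    @property
    def n_pop(self) -> int:
        return len(self.populations)

    @property
    def model(self) -> str:
        models = {p.model for p in self.neuron}
        if len(models) != 1:
            raise SpecValidationError("mixed neuron models in one network are not supported")
        return models.pop()

    @property
    def tau_m(self) -> np.ndarray:
        return np.array([p.tau_m for p in self.neuron])

    @property
    def theta(self) -> np.ndarray:
        return np.array([p.theta for p in self.neuron])

    def drive_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-population (mu_ext, sigma2_ext) of the external drive."""
        out = [dr.moments(p.tau_m) for dr, p in zip(self.drive, self.neuron)]
        mu, var = zip(*out)
        return np.array(mu), np.array(var)

    def validate(self) -> None:
        n = self.n_pop
        if n == 0:
            raise SpecValidationError("at least one population required")
        if self.N.shape != (n,):
            raise SpecValidationError("N must have one entry per population")
        if np.any(self.N < 1):
            raise SpecValidationError("population sizes N must be >= 1")
        for name, arr in (("K", self.K), ("J", self.J), ("delays", self.d)):
            if arr.shape != (n, n):
                raise SpecValidationError(f"{name} must be an {n}x{n} matrix, got shape {arr.shape}")
        if np.any(self.K < 0):
            raise SpecValidationError("in-degrees K must be >= 0")
        if np.any(self.K > self.N[None, :]):
            bad = np.argwhere(self.K > self.N[None, :])[0]
            raise SpecValidationError(
                "in-degree exceeds source population: "
                f"K[{self.populations[bad[0]]},{self.populations[bad[1]]}]="
                f"{self.K[bad[0], bad[1]]} > N_{self.populations[bad[1]]}={self.N[bad[1]]}"
            )
        if np.any(self.d < 0):
            raise SpecValidationError("delays must be >= 0")
        if len(self.neuron) != n or len(self.drive) != n:
            raise SpecValidationError("neuron and drive must be given per population")
        for p in self.neuron:
            p.validate()
        for dr in self.drive:
            dr.validate()
        _ = self.model  # uniformity check

    def copy(self) -> "NetworkSpec":
        return NetworkSpec(
            populations=list(self.populations),
            N=self.N.copy(),
            K=self.K.copy(),
            J=self.J.copy(),
            d=self.d.copy(),
            neuron=[dataclasses.replace(p) for p in self.neuron],
            drive=[dataclasses.replace(dr) for dr in self.drive],
        )


@dataclass
class WorkingPoint:
    """Self-consistent input statistics and stationary activity.

    ``mu``/``sigma`` are the mean and SD of the summed synaptic input per
    population; ``activity`` is the binary mean ``<n>`` or the firing rate in
    spikes/s; ``nu`` is the dimensionless activity used by the theory.
    """

    mu: np.ndarray
    sigma: np.ndarray
    activity: np.ndarray
    nu: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        self.activity = np.atleast_1d(np.asarray(self.activity, dtype=float))
        self.nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0")


class DefectiveConnectivityError(np.linalg.LinAlgError):
    """Raised when an operation needs an eigenbasis but W is defective."""


@dataclass
class EffectiveConnectivity:
    """Population-level effective connectivity with its eigen-decomposition.

    ``W[a, b] = (effective single-synapse weight) * K[a, b]`` quantifies the
    linearized influence of source population ``b`` on target ``a``.  Left
    and right eigenvectors are stored biorthogonally, ``v_j . u_k = d_jk``.
    """

    W: np.ndarray
    S_or_w: np.ndarray | None = None
    tau_eff: np.ndarray | None = None
    eigenvalues: np.ndarray = field(init=False)
    right_eigvecs: np.ndarray = field(init=False)  # columns u_j
    left_eigvecs: np.ndarray = field(init=False)  # rows v_j
    defective: bool = field(init=False)

    def __post_init__(self):
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        lam, U = np.linalg.eig(self.W)
        self.eigenvalues = lam
        self.right_eigvecs = U
        try:
            V = np.linalg.inv(U)
        except np.linalg.LinAlgError:
            V = np.full_like(U, np.nan)
        self.left_eigvecs = V
        recon = (U * lam) @ V
        scale = max(1.0, np.abs(self.W).max())
        self.defective = (
            not np.all(np.isfinite(V))
            or np.linalg.cond(U) > 1e12
            or np.abs(recon.real - self.W).max() > 1e-8 * scale
        )

    def require_diagonalizable(self) -> None:
        if self.defective:
            raise DefectiveConnectivityError(
                "effective connectivity is defective (non-diagonalizable); "
                "eigenmode-based operations are unavailable"
            )

    @property
    def n_pop(self) -> int:
        return self.W.shape[0]


@dataclass
class CovarianceSet:
    """Population-averaged second-order statistics.

    ``c[k]`` is the cross-covariance matrix at lag ``lags[k]`` (averaged over
    disjoint neuron pairs), ``a[k]`` the per-population autocovariance,
    ``A`` the diagonal matrix with entries ``a_alpha(0)/N_alpha`` (binary) or
    ``r_alpha/N_alpha`` (spiking).  ``C_bar[m]`` holds the complex spectral
    matrix at angular frequency ``freqs[m]`` (rad/ms).
    """

    lags: np.ndarray | None = None
    c: np.ndarray | None = None
    a: np.ndarray | None = None
    A: np.ndarray | None = None
    freqs: np.ndarray | None = None
    C_bar: np.ndarray | None = None


@dataclass
class PoleSet:
    """Poles of the propagator in the complex angular-frequency plane.

    Each entry is ``(eigenvalue index j, branch index l, z)``; a mode is
    damped when ``Im(z) > 0`` and exponentially growing when ``Im(z) < 0``.
    """

    entries: list[tuple[int, int, complex]]

    @property
    def z(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries])

    @property
    def stable(self) -> bool:
        return bool(np.all(self.z.imag > 0))

    def min_im(self) -> float:
        return float(self.z.imag.min())


# ---------------------------------------------------------------------------
# Working-point equations
# ---------------------------------------------------------------------------


def working_point_equations(spec: NetworkSpec, nu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of the summed input given dimensionless activities ``nu``.

    ``mu_a = sum_b J_ab K_ab nu_b + mu_ext_a`` and
    ``sigma_a^2 = sum_b J_ab^2 K_ab phi_b + sigma_ext_a^2`` with
    ``phi = nu (1 - nu)`` for binary populations and ``phi = nu`` for
    spiking populations (refractoriness neglected).
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (spec.n_pop,):
        raise ValueError("nu must have one entry per population")
    mu_ext, var_ext = spec.drive_moments()
    if np.any(var_ext < 0):
        raise SpecValidationError("external drive produces negative variance")
    if spec.model == "binary":
        phi = nu * (1.0 - nu)
    else:
        phi = nu
    mu = (spec.J * spec.K) @ nu + mu_ext
    var = (spec.J**2 * spec.K) @ phi + var_ext
    if np.any(var < 0):
        raise ValueError("negative input variance")
    return mu, np.sqrt(var)


def internal_variance(spec: NetworkSpec, nu: np.ndarray) -> np.ndarray:
    """Per-population input variance contributed by recurrent synapses only."""
    nu = np.asarray(nu, dtype=float)
    phi = nu * (1.0 - nu) if spec.model == "binary" else nu
    return (spec.J**2 * spec.K) @ phi


# ---------------------------------------------------------------------------
# Config I/O  (YAML schema `netscale-spec v1`)
# ---------------------------------------------------------------------------


def _as_matrix(value, n, name):
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full((n, n), float(arr))
    if arr.shape != (n, n):
        raise SpecValidationError(f"{name} must be scalar or {n}x{n}, got shape {arr.shape}")
    return arr


def _per_population(value, n, name):
    if isinstance(value, dict):
        return [value] * n
    if isinstance(value, list):
        if len(value) != n:
            raise SpecValidationError(f"{name} must have one entry per population")
        return value
    raise SpecValidationError(f"{name} must be a mapping or a list of mappings")


def network_spec_from_dict(doc: dict) -> NetworkSpec:
    if not isinstance(doc, dict) or doc.get(SCHEMA_TAG) != SCHEMA_VERSION:
        raise SpecValidationError(f"config must declare '{SCHEMA_TAG}: {SCHEMA_VERSION}'")
    try:
        populations = [str(p) for p in doc["populations"]]
        N = np.asarray(doc["N"], dtype=int)
    except KeyError as exc:
        raise SpecValidationError(f"missing required key {exc}") from exc
    n = len(populations)
    if "K" in doc:
        K = _as_matrix(doc["K"], n, "K")
    elif "p" in doc:
        p = _as_matrix(doc["p"], n, "p")
        if np.any((p < 0) | (p > 1)):
            raise SpecValidationError("connection probabilities p must lie in [0, 1]")
        K = _round_half_up(p * N[None, :])
    else:
        raise SpecValidationError("config must provide either 'K' or 'p'")
    J = _as_matrix(doc.get("J", 0.0), n, "J")
    d = _as_matrix(doc.get("delays", 0.0), n, "delays")
    neuron = [NeuronParams(**m) for m in _per_population(doc.get("neuron"), n, "neuron")]
    drive = [Drive(**m) for m in _per_population(doc.get("drive", {"kind": "dc"}), n, "drive")]
    return NetworkSpec(populations=populations, N=N, K=K, J=J, d=d, neuron=neuron, drive=drive)


def network_spec_to_dict(spec: NetworkSpec) -> dict:
    def clean(obj):
        out = {}
        for k, v in dataclasses.asdict(obj).items():
            if isinstance(v, (np.floating, np.integer)):
                v = v.item()
            out[k] = v
        return out

    return {
        SCHEMA_TAG: SCHEMA_VERSION,
        "populations": list(spec.populations),
        "N": spec.N.tolist(),
        "K": spec.K.tolist(),
        "J": spec.J.tolist(),
        "delays": spec.d.tolist(),
        "neuron": [clean(p) for p in spec.neuron],
        "drive": [clean(dr) for dr in spec.drive],
    }


def load_network_spec(path) -> NetworkSpec:
    """Load and validate a network config (YAML, schema ``netscale-spec v1``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return network_spec_from_dict(doc)


def save_network_spec(spec: NetworkSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(network_spec_to_dict(spec), sort_keys=False))
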