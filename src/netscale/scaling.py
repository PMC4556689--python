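"""Network scaling transformations and their feasibility limits.

The temporal structure of pairwise averaged covariances is fixed by the
effective connectivity W, so a downscaling of in-degrees K that preserves
covariances must trade synaptic weight against in-degree (J ∝ 1/K) and
restore the working point by adjusting the external drive.  Shrinking K
raises the internally generated input variance, which must be compensated by
*reducing* the external variance — possible only down to

    kappa_min = sigma_int^2 / (sigma_int^2 + sigma_ext^2),

the fundamental limit implemented here.  Two special-case transformations
that trade structure for size under weaker requirements (zero-lag-only
preservation in symmetric binary networks; the zero-eigenvalue degenerate
spiking network) are also provided.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, root

from . import binary as bt
from . import lif as lt
from .core import Drive, NetworkSpec, WorkingPoint, internal_variance

__all__ = [
    "ScalingResult",
    "min_kappa",
    "scale_jk",
    "poisson_ei_drive_rates",
    "binary_generic_scaling_drive",
    "binary_symmetric_parameters",
    "binary_zero_lag_covariance",
    "binary_zero_lag_scaling",
    "symmetric_spiking_scaling",
]


@dataclass
class ScalingResult:
    """A transformed network plus feasibility diagnostics."""

    scaled_spec: NetworkSpec | None
    kappa: float
    iota: float
    N_factor: float
    feasible: bool
    reason: str = ""
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# The in-degree scaling limit
# ---------------------------------------------------------------------------


def min_kappa(spec: NetworkSpec, wp: WorkingPoint):
    """Minimal in-degree scaling factor per population and overall.

    ``kappa_a = sigma2_int_a / (sigma2_int_a + sigma2_ext_a)``; the overall
    limit is the maximum over populations (the binding constraint).
    """
    s2_int = internal_variance(spec, wp.nu)
    _, s2_ext = spec.drive_moments()
    total = s2_int + s2_ext
    if np.any(total <= 0):
        raise ValueError("zero total input variance")
    per_pop = s2_int / total
    return per_pop, float(per_pop.max())


# ---------------------------------------------------------------------------
# J ∝ 1/K scaling with drive adjustment (spiking networks)
# ---------------------------------------------------------------------------


def poisson_ei_drive_rates(r_e0: float, iota: float, sigma2_int: float, tau_m: float,
                           J_ext: float, g: float):
    """Excitatory/inhibitory Poisson rates that keep the mean drive fixed
    while absorbing the internal-variance change ``(1 - iota) sigma2_int``
    (usable for upscaling only; downscaling needs a negative inhibitory
    rate).  ``tau_m`` in ms; rates in spikes/s."""
    tm = tau_m * 1e-3
    extra = (1.0 - iota) * sigma2_int / (tm * J_ext**2)
    r_e = r_e0 + extra / (1.0 + g)
    r_i = extra / (g * (1.0 + g))
    return r_e, r_i


def scale_jk(spec: NetworkSpec, kappa: float, N_factor: float = 1.0,
             J_ext: float | None = None, wp: WorkingPoint | None = None) -> ScalingResult:
    """Scale in-degrees by ``kappa`` with ``J ∝ 1/K`` and adjust the drive.

    In-degrees are rounded to integers and the weights compensate the
    rounding exactly (``J' = J K / K'``), so W is preserved entrywise.  The
    drive is replaced by a balanced Poisson drive (equal excitatory and
    inhibitory rates, weights ``±J_ext``) generating the required external
    variance plus a DC current reproducing the external mean.  Infeasible
    requests (required variance < 0) are returned flagged, not clipped.
    """
    if spec.model != "lif":
        raise ValueError("scale_jk operates on spiking networks; "
                         "use binary_generic_scaling_drive for binary ones")
    if kappa <= 0 or N_factor <= 0:
        raise ValueError("kappa and N_factor must be > 0")
    if wp is None:
        wp = lt.solve_rates(spec)
    K_new = np.round(kappa * spec.K)
    with np.errstate(divide="ignore", invalid="ignore"):
        J_new = np.where(K_new > 0, spec.J * spec.K / np.maximum(K_new, 1), 0.0)
    N_new = np.maximum(np.round(N_factor * spec.N).astype(int), 1)
    iota = 1.0 / kappa

    mu_ext, s2_ext = spec.drive_moments()
    phi = wp.nu
    s2_int_new = (J_new**2 * K_new) @ phi
    s2_int_old = internal_variance(spec, wp.nu)
    s2_ext_new = s2_int_old + s2_ext - s2_int_new  # preserve total variance

    drives = []
    feasible = True
    reason = ""
    tm = spec.tau_m * 1e-3
    for a in range(spec.n_pop):
        je = spec.drive[a].J_ext if J_ext is None else J_ext
        rate = s2_ext_new[a] / (2.0 * tm[a] * je**2)
        if s2_ext_new[a] < 0:
            feasible = False
            reason = (f"required external variance is negative for population "
                      f"{spec.populations[a]} ({s2_ext_new[a]:.3f}); kappa below kappa_min")
        drives.append(Drive(kind="poisson_balanced", rate_e=max(rate, 0.0),
                            rate_i=max(rate, 0.0), J_ext=je, g_ext=1.0, I_dc=mu_ext[a]))

    scaled = None
    if feasible:
        scaled = NetworkSpec(
            populations=list(spec.populations), N=N_new, K=K_new, J=J_new,
            d=spec.d.copy(), neuron=[dataclasses.replace(p) for p in spec.neuron],
            drive=drives,
        )
    W_drift = float(np.abs(J_new * K_new - spec.J * spec.K).max())
    return ScalingResult(
        scaled_spec=scaled, kappa=kappa, iota=iota, N_factor=N_factor,
        feasible=feasible, reason=reason,
        diagnostics={
            "sigma2_ext_new": s2_ext_new,
            "sigma2_int_old": s2_int_old,
            "sigma2_int_new": s2_int_new,
            "JK_drift": W_drift,
            "working_point_mu": wp.mu,
            "working_point_sigma": wp.sigma,
        },
    )


# ---------------------------------------------------------------------------
# Generic binary scaling (kappa, iota) preserving mean activities
# ---------------------------------------------------------------------------


def binary_generic_scaling_drive(spec: NetworkSpec, wp: WorkingPoint,
                                 kappa: float, iota: float):
    """External variance required to keep S'J'K' = SJK under K' = kappa K,
    J' = iota J for a binary network with Heaviside gain:

        sigma2_ext' = iota^2 kappa [ (kappa - 1) sigma2_int + kappa sigma2_ext ]

    (the internal SD scales as ``iota sqrt(kappa) sigma_int`` when mean
    activities are preserved).  A negative value flags infeasibility.
    """
    if spec.model != "binary":
        raise ValueError("binary_generic_scaling_drive requires a binary network")
    s2_int = internal_variance(spec, wp.nu)
    _, s2_ext = spec.drive_moments()
    return iota**2 * kappa * ((kappa - 1.0) * s2_int + kappa * s2_ext)


# ---------------------------------------------------------------------------
# Symmetric-structure helpers
# ---------------------------------------------------------------------------


def binary_symmetric_parameters(spec: NetworkSpec):
    """Extract (N, gamma, K, J, g) from a two-population network with the
    symmetric structure J = [[J, -gJ], [J, -gJ]], K = [[K, gamma K], ...]."""
    if spec.n_pop != 2:
        raise ValueError("symmetric structure requires exactly two populations")
    J = spec.J[0, 0]
    K = spec.K[0, 0]
    if not (np.allclose(spec.J[:, 0], J) and np.allclose(spec.K[:, 0], K)):
        raise ValueError("rows must share the excitatory weight and in-degree")
    g = -spec.J[0, 1] / J
    gamma = spec.N[1] / spec.N[0]
    if not (np.allclose(spec.J[:, 1], -g * J) and np.allclose(spec.K[:, 1], gamma * K)):
        raise ValueError("network does not have the symmetric two-population structure")
    return int(spec.N[0]), float(gamma), float(K), float(J), float(g)


def _zero_lag_system(We: float, g: float, gamma: float, a: float, N: float):
    """Matrix and RHS of the zero-lag self-consistency for (c_ee, c_ii):
    [1 - We/2 * [[2-gamma g, -gamma g], [1, 1-2 gamma g]]] c = We a/N (1, -g)."""
    M = np.eye(2) - 0.5 * We * np.array(
        [[2.0 - gamma * g, -gamma * g], [1.0, 1.0 - 2.0 * gamma * g]]
    )
    rhs = We * a / N * np.array([1.0, -g])
    return M, rhs


def binary_zero_lag_covariance(spec: NetworkSpec, wp: WorkingPoint | None = None):
    """Zero-lag pair-averaged covariances (c_ee, c_ii) of a symmetric binary
    network, with c_ei = c_ie = (c_ee + c_ii)/2."""
    if wp is None:
        wp = bt.mean_activity(spec)
    N, gamma, K, J, g = binary_symmetric_parameters(spec)
    S = bt.susceptibility(wp.mu[0], wp.sigma[0], spec.theta[0])
    We = S * J * K
    a = float(wp.activity[0] * (1.0 - wp.activity[0]))
    M, rhs = _zero_lag_system(We, g, gamma, a, N)
    cee, cii = np.linalg.solve(M, rhs)
    return float(cee), float(cii), float(We), a


def binary_zero_lag_scaling(spec: NetworkSpec, N_prime: float) -> ScalingResult:
    """Rescale a symmetric binary network to excitatory size ``N_prime``
    while preserving mean activities and zero-lag covariances.

    Keeps gamma fixed and solves for the in-degree factor ``f``
    (W_e -> f W_e, realized as K -> f K) and the new relative inhibitory
    weight ``g'`` such that the zero-lag system at size N' reproduces the
    original (c_ee, c_ii).  The working point is restored by an added
    Gaussian drive with

        mu_ext  = K J (1 - gamma g) <n> - f K J (1 - gamma g') <n>
        s2_ext  = K J^2 (1 + gamma g^2) a - f K J^2 (1 + gamma g'^2) a

    Fails (flagged, not clipped) at the bifurcation g' <= 1/gamma or when
    the required external variance is negative.
    """
    wp = bt.mean_activity(spec)
    N, gamma, K, J, g = binary_symmetric_parameters(spec)
    cee, cii, We, a = binary_zero_lag_covariance(spec, wp)
    n_mean = float(wp.activity[0])

    def resid(x):
        Wp, gp = x
        M, rhs = _zero_lag_system(Wp, gp, gamma, a, N_prime)
        return M @ np.array([cee, cii]) - rhs

    sol = root(resid, np.array([We, g]), method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-12 * max(abs(cee), abs(cii)):
        raise RuntimeError("zero-lag scaling equations did not converge")
    W_new, g_new = sol.x
    f = W_new / We

    mu_ext = K * J * (1.0 - gamma * g) * n_mean - f * K * J * (1.0 - gamma * g_new) * n_mean
    s2_ext = K * J**2 * (1.0 + gamma * g**2) * a - f * K * J**2 * (1.0 + gamma * g_new**2) * a

    diagnostics = {"f": f, "g_prime": g_new, "c_ee": cee, "c_ii": cii,
                   "mu_ext": mu_ext, "sigma2_ext": s2_ext, "W_e": We}
    if g_new <= 1.0 / gamma:
        return ScalingResult(None, kappa=f, iota=1.0, N_factor=N_prime / N,
                             feasible=False,
                             reason=f"bifurcation: g' = {g_new:.4f} <= 1/gamma = {1/gamma:.4f}",
                             diagnostics=diagnostics)
    if s2_ext < 0:
        return ScalingResult(None, kappa=f, iota=1.0, N_factor=N_prime / N,
                             feasible=False,
                             reason=f"required external variance negative ({s2_ext:.4f})",
                             diagnostics=diagnostics)

    base_mu, _ = spec.drive_moments()
    K_new = f * K
    scaled = NetworkSpec(
        populations=list(spec.populations),
        N=np.maximum(np.round([N_prime, gamma * N_prime]).astype(int), 1),
        K=np.array([[K_new, gamma * K_new], [K_new, gamma * K_new]]),
        J=np.array([[J, -g_new * J], [J, -g_new * J]]),
        d=spec.d.copy(),
        neuron=[dataclasses.replace(p) for p in spec.neuron],
        drive=[Drive(kind="gaussian", mu_ext=base_mu[a_] + mu_ext,
                     sigma_ext=float(np.sqrt(s2_ext))) for a_ in range(2)],
    )
    return ScalingResult(scaled, kappa=f, iota=1.0, N_factor=N_prime / N,
                         feasible=True, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Degenerate (zero-eigenvalue) symmetric spiking network
# ---------------------------------------------------------------------------


def _lif_covariance_coefficient(W: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Matrix of lag-course coefficients sum_jk A^jk l_j(2-l_j)/(2-l_j-l_k)
    u_j u_k^T — equality of this matrix (the nonzero eigenvalue L is shared)
    implies equality of the full delay-free covariance course."""
    lam, U = np.linalg.eig(W)
    V = np.linalg.inv(U)
    Ajk = V @ A @ V.T
    coeff = Ajk * (lam[:, None] * (2.0 - lam[:, None])) / (2.0 - lam[:, None] - lam[None, :])
    return np.einsum("jk,aj,bk->ab", coeff, U, U).real


def symmetric_spiking_scaling(spec: NetworkSpec, wK_prime: float,
                              wp: WorkingPoint | None = None,
                              x0=None) -> ScalingResult:
    """Scale the degenerate symmetric two-population LIF network.

    The rank-one effective connectivity W = wK [[1, -gamma g], [1, -gamma g]]
    has eigenvalues {L, 0}; the zero eigenvalue leaves freedom to change the
    eigenvectors while preserving all covariances.  Given the target
    ``w'K'``, solves the four covariance-matching conditions for the new
    population sizes N1, N2 and the shape parameter c of
    ``W' = w'K' [[1, -b], [c, -bc]]`` (with b fixed by eigenvalue
    preservation); the known exact solution has c = 1, used as a cross-check.
    Returns gamma' = N2/N1, g' = (w'K' - L)/(w'K' gamma') and the drive that
    restores the working point.
    """
    if spec.model != "lif":
        raise ValueError("symmetric_spiking_scaling requires an lif network")
    if wp is None:
        wp = lt.solve_rates(spec)
    N, gamma, K, J, g = binary_symmetric_parameters(spec)
    if np.abs(spec.d).max() > 0:
        raise ValueError("the degenerate scaling assumes vanishing delays")
    w = lt.effective_weight(J, wp.mu[0], wp.sigma[0], spec.neuron[0], order=2)
    L = w * K * (1.0 - gamma * g)
    wK = w * K
    r = float(wp.activity[0])  # statistically identical populations
    A_old = np.diag([r / N, r / (gamma * N)])
    W_old = wK * np.array([[1.0, -gamma * g], [1.0, -gamma * g]])
    B_old = _lif_covariance_coefficient(W_old, A_old)

    def build(x):
        N1, N2, c = x
        b = (1.0 - L / wK_prime) / c
        Wn = wK_prime * np.array([[1.0, -b], [c, -b * c]])
        An = np.diag([r / N1, r / N2])
        return Wn, An

    def resid(x):
        if x[0] <= 0 or x[1] <= 0 or abs(x[2]) < 1e-12:
            return np.full(4, 1e6)
        Wn, An = build(x)
        return (_lif_covariance_coefficient(Wn, An) - B_old).ravel() / max(np.abs(B_old).max(), 1e-300)

    # The matching conditions are linear in (1/N1, 1/N2) once the shape
    # parameter c is fixed; c = 1 solves them exactly (the zero-eigenvalue
    # freedom), so a least-squares solve in the inverse sizes is exact.
    if x0 is None:
        b1 = 1.0 - L / wK_prime
        Wn1 = wK_prime * np.array([[1.0, -b1], [1.0, -b1]])
        basis = np.column_stack([
            _lif_covariance_coefficient(Wn1, np.diag([r, 0.0])).ravel(),
            _lif_covariance_coefficient(Wn1, np.diag([0.0, r])).ravel(),
        ])
        x_inv, *_ = np.linalg.lstsq(basis, B_old.ravel(), rcond=None)
        lin_res = np.abs(basis @ x_inv - B_old.ravel()).max() / np.abs(B_old).max()
        if np.any(x_inv <= 0) or lin_res > 1e-8:
            N1, N2 = np.where(x_inv != 0, 1.0 / x_inv, np.inf)
            c = 1.0
            gamma_new = N2 / N1
            g_new = (wK_prime - L) / (wK_prime * gamma_new)
            return ScalingResult(
                None, kappa=wK_prime / wK, iota=1.0, N_factor=N1 / N,
                feasible=False,
                reason=(f"no positive-size solution (N1={N1:.1f}, N2={N2:.1f}, "
                        f"g'={g_new:.4f}); sizes diverge as g' approaches zero"),
                diagnostics={"N1": N1, "N2": N2, "c": c, "gamma_prime": gamma_new,
                             "g_prime": g_new, "residual": lin_res, "L": L, "w": w},
            )
        start = np.array([1.0 / x_inv[0], 1.0 / x_inv[1], 1.0])
    else:
        start = np.asarray(x0, dtype=float)
    sol = least_squares(resid, start, method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    N1, N2, c = sol.x
    res = np.max(np.abs(sol.fun))
    gamma_new = N2 / N1
    g_new = (wK_prime - L) / (wK_prime * gamma_new)
    diagnostics = {
        "N1": N1, "N2": N2, "c": c, "gamma_prime": gamma_new, "g_prime": g_new,
        "residual": res, "L": L, "w": w,
        "n_neurons_total": (1.0 + gamma_new) * N1,
        "n_synapses_total": (1.0 + gamma_new) ** 2 * (wK_prime / w) * N1,
    }
    if res > 1e-7:
        return ScalingResult(None, kappa=wK_prime / wK, iota=1.0, N_factor=N1 / N,
                             feasible=False, reason=f"no solution (residual {res:.2e})",
                             diagnostics=diagnostics)
    if g_new <= 0 or not np.isfinite(N1 + N2) or N1 < 1 or N2 < 1:
        return ScalingResult(None, kappa=wK_prime / wK, iota=1.0, N_factor=N1 / N,
                             feasible=False,
                             reason=f"diverging sizes or g' = {g_new:.4f} <= 0",
                             diagnostics=diagnostics)

    K_new = wK_prime / w  # realize w'K' with w' = w
    s2_int_new = (J**2 * K_new + (g_new * J) ** 2 * gamma_new * K_new) * wp.nu[0]
    mu_int_new = (J * K_new - g_new * J * gamma_new * K_new) * wp.nu[0]
    s2_ext_new = wp.sigma[0] ** 2 - s2_int_new
    mu_ext_new = wp.mu[0] - mu_int_new
    tm = spec.neuron[0].tau_m * 1e-3
    J_ext = spec.drive[0].J_ext
    rate = s2_ext_new / (2.0 * tm * J_ext**2)
    diagnostics.update({"sigma2_ext": s2_ext_new, "mu_ext": mu_ext_new,
                        "poisson_rate": rate, "drive_feasible": bool(s2_ext_new >= 0)})
    if s2_ext_new < 0:
        # the covariance-preserving transformation itself exists; only the
        # working point cannot be supplied by a non-negative-variance drive
        return ScalingResult(None, kappa=wK_prime / wK, iota=1.0, N_factor=N1 / N,
                             feasible=False,
                             reason=f"required external variance negative ({s2_ext_new:.3f})",
                             diagnostics=diagnostics)
    scaled = NetworkSpec(
        populations=list(spec.populations),
        N=np.maximum(np.round([N1, N2]).astype(int), 1),
        K=np.array([[K_new, gamma_new * K_new], [K_new, gamma_new * K_new]]),
        J=np.array([[J, -g_new * J], [J, -g_new * J]]),
        d=spec.d.copy(),
        neuron=[dataclasses.replace(p) for p in spec.neuron],
        drive=[Drive(kind="poisson_balanced", rate_e=rate, rate_i=rate,
                     J_ext=J_ext, g_ext=1.0, I_dc=mu_ext_new) for _ in range(2)],
    )
    return ScalingResult(scaled, kappa=wK_prime / wK, iota=1.0, N_factor=N1 / N,
                         feasible=True, diagnostics=diagnostics)
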