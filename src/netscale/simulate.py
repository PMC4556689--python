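"""Reference simulators and covariance estimation.

The binary simulator is event-driven: each neuron is updated at independent
Poisson times with rate ``1/tau``; on update the state becomes the Heaviside
function of recurrent input plus a fresh Gaussian external sample.  The LIF
simulator is clock-driven with exact subthreshold integration of the
membrane/synapse linear system; spikes are constrained to the time grid.
Connectivity has fixed in-degrees, no multapses and no autapses.  The
estimator averages cross-covariances over all pairs across two disjoint
neuron groups per population, and autocovariances over a stated subset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .core import NetworkSpec, network_spec_to_dict

__all__ = [
    "SimulationOutput",
    "MeasuredCovariance",
    "build_connectivity",
    "simulate_binary",
    "simulate_lif",
    "measure_covariances",
]


def spec_hash(spec: NetworkSpec) -> str:
    doc = json.dumps(network_spec_to_dict(spec), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _derive_seed(seed: int, purpose: str) -> int:
    h = hashlib.sha256(f"{seed}:{purpose}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class SimulationOutput:
    """Raw output of a network simulation.

    For binary runs, ``states`` holds the recorded subset of neuron states
    sampled every ``dt`` ms (rows: sample times) and ``pop_counts`` the
    number of active neurons per population on the same grid.  For spiking
    runs, ``spikes`` is an ``(n_spikes, 2)`` array of (neuron id, time ms)
    after the burn-in and ``spike_counts`` the per-neuron totals.
    """

    kind: str  # "binary_trace" | "spike_trains"
    T: float
    dt: float
    seed: int
    spec_hash: str
    pop_sizes: np.ndarray
    pop_of: np.ndarray
    burn_in: float = 0.0
    mean_activity: np.ndarray | None = None
    pop_counts: np.ndarray | None = None
    states: np.ndarray | None = None
    record_ids: np.ndarray | None = None
    spikes: np.ndarray | None = None
    spike_counts: np.ndarray | None = None

    @property
    def rates(self) -> np.ndarray:
        """Per-population mean firing rate in spikes/s (spiking runs)."""
        if self.spike_counts is None:
            raise ValueError("rates require a spiking run with spike counts")
        T_eff = (self.T - self.burn_in) * 1e-3
        out = np.empty(self.pop_sizes.size)
        start = 0
        for p, n in enumerate(self.pop_sizes):
            out[p] = self.spike_counts[start : start + n].sum() / (n * T_eff)
            start += n
        return out


@dataclass
class MeasuredCovariance:
    """Estimated population-averaged covariance functions.

    ``c_hat[k, a, b]`` is the average cross-covariance between disjoint
    groups of populations a and b at lag ``lags[k]``; ``a_hat[k, a]`` the
    average single-neuron autocovariance; ``sem`` block-wise standard
    errors of ``c_hat``.
    """

    lags: np.ndarray
    c_hat: np.ndarray
    a_hat: np.ndarray
    sem: np.ndarray
    bin: float


def _integer_indegrees(spec: NetworkSpec) -> np.ndarray:
    return np.round(spec.K).astype(np.int64)


def build_connectivity(spec: NetworkSpec, seed: int):
    """Fixed in-degree adjacency (CSR by source): (indptr, targets)."""
    N_sizes = spec.N.astype(np.int64)
    offsets = np.concatenate([[0], np.cumsum(N_sizes)]).astype(np.int64)
    K_int = _integer_indegrees(spec)
    if np.any(K_int > N_sizes[None, :] - (np.eye(spec.n_pop, dtype=int))):
        raise ValueError("in-degree too large for autapse-free connectivity")
    return _kernels.sample_fixed_indegree(
        N_sizes, offsets, K_int, _derive_seed(seed, "connectivity"), False
    )


def _pop_labels(spec: NetworkSpec) -> np.ndarray:
    return np.concatenate(
        [np.full(n, i, dtype=np.int64) for i, n in enumerate(spec.N)]
    )


def simulate_binary(
    spec: NetworkSpec,
    T: float,
    seed: int,
    sample_dt: float = 0.3,
    burn_in: float | None = None,
    record_ids: np.ndarray | None = None,
    init_active_fraction: float = 0.0,
) -> SimulationOutput:
    """Event-driven simulation of a binary network for ``T`` ms.

    ``record_ids`` selects neurons whose states are stored on the
    ``sample_dt`` grid (default: all neurons if the state matrix stays below
    ~100 MB, otherwise none).  Gaussian externals are sampled independently
    at every update event.
    """
    if spec.model != "binary":
        raise ValueError("simulate_binary requires a binary network")
    for dr in spec.drive:
        if dr.kind == "poisson_balanced":
            raise ValueError("binary networks take gaussian or dc drive")
    burn_in = min(500.0, 0.1 * T) if burn_in is None else burn_in
    mu_ext, var_ext = spec.drive_moments()
    indptr, targets = build_connectivity(spec, seed)
    pop_of = _pop_labels(spec)
    if record_ids is None:
        n_samples = int(T / sample_dt) + 1
        total = int(spec.N.sum())
        record_ids = (
            np.arange(total, dtype=np.int64)
            if n_samples * total <= 100_000_000
            else np.empty(0, dtype=np.int64)
        )
    record_ids = np.asarray(record_ids, dtype=np.int64)
    rng = np.random.default_rng(_derive_seed(seed, "init"))
    init = (rng.random(pop_of.size) < init_active_fraction).astype(np.int8)
    mean_act, pop_counts, rec_states = _kernels.run_binary(
        pop_of,
        spec.N.astype(np.float64),
        indptr,
        targets,
        spec.J,
        spec.theta.astype(float),
        mu_ext,
        np.sqrt(var_ext),
        float(spec.tau_m[0]),
        float(T),
        float(burn_in),
        _derive_seed(seed, "dynamics"),
        float(sample_dt),
        record_ids,
        init,
    )
    return SimulationOutput(
        kind="binary_trace",
        T=float(T),
        dt=float(sample_dt),
        seed=seed,
        spec_hash=spec_hash(spec),
        pop_sizes=spec.N.copy(),
        pop_of=pop_of,
        burn_in=float(burn_in),
        mean_activity=mean_act,
        pop_counts=pop_counts,
        states=rec_states,
        record_ids=record_ids,
    )


def simulate_lif(
    spec: NetworkSpec,
    T: float,
    dt: float = 0.1,
    seed: int = 0,
    burn_in: float | None = None,
    record: str = "spikes",
    max_spikes: int | None = None,
) -> SimulationOutput:
    """Clock-driven simulation of an LIF network for ``T`` ms.

    All delays must be integer multiples of ``dt`` and at least ``dt``.
    Gaussian drive specifications are realized as an equivalent balanced
    Poisson drive plus DC (diffusion approximation) with weight
    ``drive.J_ext``; ``record="counts"`` skips storing spike times.
    """
    if spec.model != "lif":
        raise ValueError("simulate_lif requires an lif network")
    if np.any(spec.d < dt - 1e-12):
        raise ValueError("delays must be at least one time step")
    if np.any(np.abs(np.round(spec.d / dt) - spec.d / dt) > 1e-9):
        raise ValueError("dt must divide all delays")
    burn_in = min(500.0, 0.1 * T) if burn_in is None else burn_in
    npop = spec.n_pop
    lam_e = np.zeros(npop)
    lam_i = np.zeros(npop)
    J_ext = np.zeros(npop)
    g_ext = np.ones(npop)
    I_dc = np.zeros(npop)
    for p, dr in enumerate(spec.drive):
        if dr.kind == "poisson_balanced":
            lam_e[p] = dr.rate_e * dt * 1e-3
            lam_i[p] = dr.rate_i * dt * 1e-3
            J_ext[p] = dr.J_ext
            g_ext[p] = dr.g_ext
            I_dc[p] = dr.I_dc
        elif dr.kind == "gaussian":
            # balanced-Poisson realization of the requested moments
            tm = spec.neuron[p].tau_m * 1e-3
            rate = dr.sigma_ext**2 / (2.0 * tm * dr.J_ext**2)
            lam_e[p] = lam_i[p] = rate * dt * 1e-3
            J_ext[p] = dr.J_ext
            I_dc[p] = dr.mu_ext
        else:  # dc
            I_dc[p] = dr.I_dc
    indptr, targets = build_connectivity(spec, seed)
    pop_of = _pop_labels(spec)
    n_steps = int(round(T / dt))
    burn_steps = int(round(burn_in / dt))
    record_spikes = record == "spikes"
    if max_spikes is None:
        max_spikes = int(spec.N.sum() * (T - burn_in) * 1e-3 * 100) + 1000
    counts, spk_n, spk_s, overflow = _kernels.run_lif(
        pop_of,
        indptr,
        targets,
        spec.J,
        np.round(spec.d / dt).astype(np.int64),
        spec.tau_m.astype(float),
        np.array([p.tau_s for p in spec.neuron], dtype=float),
        np.array([p.tau_ref for p in spec.neuron], dtype=float),
        spec.theta.astype(float),
        np.array([p.V_r for p in spec.neuron], dtype=float),
        I_dc,
        lam_e,
        lam_i,
        J_ext,
        g_ext,
        float(dt),
        n_steps,
        burn_steps,
        _derive_seed(seed, "dynamics"),
        max_spikes,
        record_spikes,
    )
    if overflow:
        raise RuntimeError("spike record overflow; raise max_spikes or use record='counts'")
    spikes = None
    if record_spikes:
        spikes = np.column_stack([spk_n.astype(float), spk_s * dt])
    return SimulationOutput(
        kind="spike_trains",
        T=float(T),
        dt=float(dt),
        seed=seed,
        spec_hash=spec_hash(spec),
        pop_sizes=spec.N.copy(),
        pop_of=pop_of,
        burn_in=float(burn_in),
        spikes=spikes,
        spike_counts=counts,
    )


# ---------------------------------------------------------------------------
# Covariance estimation
# ---------------------------------------------------------------------------


def _signals_from_output(out: SimulationOutput, bin_ms: float):
    """Per-neuron signal matrix (neurons x bins) and the signal scale.

    Binary states are resampled by decimation to the requested bin; spike
    trains are binned into rate signals (counts / bin, in spikes/s).
    """
    if out.kind == "binary_trace":
        if out.states is None or out.states.size == 0:
            raise ValueError("binary run recorded no states")
        stride = max(1, int(round(bin_ms / out.dt)))
        skip = int(np.ceil(out.burn_in / out.dt))
        sig = out.states[skip::stride].T.astype(np.float64)
        ids = out.record_ids
        return sig, ids, stride * out.dt
    if out.spikes is None:
        raise ValueError("spiking run has no recorded spike times")
    n_bins = int((out.T - out.burn_in) / bin_ms)
    total = int(out.pop_sizes.sum())
    sig = np.zeros((total, n_bins))
    t0 = out.burn_in
    idx = ((out.spikes[:, 1] - t0) / bin_ms).astype(np.int64)
    ok = (idx >= 0) & (idx < n_bins)
    np.add.at(sig, (out.spikes[ok, 0].astype(np.int64), idx[ok]), 1.0)
    sig /= bin_ms * 1e-3  # spikes/s
    return sig, np.arange(total), bin_ms


def _xcov(x: np.ndarray, y: np.ndarray, max_shift: int) -> np.ndarray:
    """Unbiased cross-covariance <dx(t+k) dy(t)> for k in [-max_shift, max_shift]."""
    n = x.size
    dx = x - x.mean()
    dy = y - y.mean()
    m = 1
    while m < 2 * n:
        m *= 2
    fx = np.fft.rfft(dx, m)
    fy = np.fft.rfft(dy, m)
    full = np.fft.irfft(fx * np.conj(fy), m)
    out = np.empty(2 * max_shift + 1)
    for i, k in enumerate(range(-max_shift, max_shift + 1)):
        out[i] = full[k % m] / (n - abs(k))
    return out


def measure_covariances(
    out: SimulationOutput,
    bin: float,
    max_lag: float,
    group_size: int | None = None,
    n_auto: int = 100,
    n_blocks: int = 8,
) -> MeasuredCovariance:
    """Estimate population-averaged covariance functions from a simulation.

    For each population pair, the cross-covariance is the covariance between
    the mean signals of two disjoint neuron groups (equal to the average
    over all cross pairs); the pair set is shared between (a, b) and (b, a),
    so the symmetry ``c_ab(D) = c_ba(-D)`` is exact by construction.
    Autocovariances average ``n_auto`` single neurons per population.  SEM
    is estimated from ``n_blocks`` consecutive time blocks.
    """
    sig, ids, eff_bin = _signals_from_output(out, bin)
    npop = out.pop_sizes.size
    pop_of_rec = out.pop_of[ids]
    max_shift = int(round(max_lag / eff_bin))
    lags = np.arange(-max_shift, max_shift + 1) * eff_bin
    groups = []
    for p in range(npop):
        members = np.where(pop_of_rec == p)[0]
        half = len(members) // 2
        gs = min(group_size or half, half)
        if gs < 1:
            raise ValueError(f"population {p} has too few recorded neurons for two groups")
        groups.append((members[:gs], members[gs : 2 * gs]))
    mean_sig = np.array(
        [[sig[g].mean(axis=0) for g in pair] for pair in groups]
    )  # (npop, 2, n_bins)
    n_bins = mean_sig.shape[-1]
    c_hat = np.empty((lags.size, npop, npop))
    sem = np.empty_like(c_hat)
    block_len = n_bins // n_blocks
    for a in range(npop):
        for b in range(a, npop):
            x = mean_sig[a][0]
            y = mean_sig[b][1]
            cc = _xcov(x, y, max_shift)
            c_hat[:, a, b] = cc
            c_hat[:, b, a] = cc[::-1]
            blocks = np.array(
                [
                    _xcov(
                        x[i * block_len : (i + 1) * block_len],
                        y[i * block_len : (i + 1) * block_len],
                        max_shift,
                    )
                    for i in range(n_blocks)
                ]
            )
            s = blocks.std(axis=0, ddof=1) / np.sqrt(n_blocks)
            sem[:, a, b] = s
            sem[:, b, a] = s[::-1]
    a_hat = np.empty((lags.size, npop))
    for p in range(npop):
        members = np.where(pop_of_rec == p)[0][:n_auto]
        acc = np.zeros(lags.size)
        for j in members:
            acc += _xcov(sig[j], sig[j], max_shift)
        a_hat[:, p] = acc / len(members)
    return MeasuredCovariance(lags=lags, c_hat=c_hat, a_hat=a_hat, sem=sem, bin=eff_bin)
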