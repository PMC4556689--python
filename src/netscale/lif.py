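"""Mean-field theory of leaky integrate-and-fire (LIF) networks.

The stationary rate of an LIF neuron with exponential current synapses under
Gaussian input noise follows the mean-first-passage-time (Siegert) formula
with integration boundaries shifted by ``(alpha/2) sqrt(tau_s/tau_m)``,
``alpha = sqrt(2) |zeta(1/2)|``, to account for the short synaptic filtering
time.  The linear response around the working point is approximated by a
delayed one-pole (low-pass) kernel, which yields closed-form cross-spectra
and, for delay-free uniform networks, a closed-form covariance time course.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import root
from scipy.special import erfcx, zeta

from .core import (
    CovarianceSet,
    EffectiveConnectivity,
    NetworkSpec,
    NeuronParams,
    PoleSet,
    WorkingPoint,
    working_point_equations,
)
from .binary import (
    UnstableNetworkError,
    _eigen_checks,
    _mode_amplitudes,
    characteristic_residual,
    delayed_poles,
    transfer_matrix,
)

__all__ = [
    "siegert_rate",
    "siegert_derivatives",
    "solve_rates",
    "effective_weight",
    "effective_connectivity_lif",
    "autocovariance_diagonal_lif",
    "cross_spectrum_lif",
    "covariance_time_lif",
    "pole_spectrum",
]

ALPHA = float(np.sqrt(2.0) * abs(zeta(0.5)))  # boundary-shift constant

# beyond this bound the Gaussian-tail integral makes the rate numerically zero
_MAX_BOUND = 26.0


def _psi(s):
    """``Psi(s) = e^{s^2}(1 + erf(s)) = erfcx(-s)``, overflow-safe for s < 0."""
    return erfcx(-s)


def siegert_rate(mu: float, sigma: float, params: NeuronParams) -> float:
    """Stationary firing rate (spikes/s) of an LIF neuron for Gaussian input
    with mean ``mu`` and SD ``sigma`` (mV).

    The deterministic limit ``sigma -> 0`` returns the closed-form
    suprathreshold rate for ``mu > theta`` and 0 otherwise.
    """
    if params.model != "lif":
        raise ValueError("siegert_rate requires lif neuron parameters")
    tau_m = params.tau_m * 1e-3  # s
    tau_s = params.tau_s * 1e-3
    tau_ref = params.tau_ref * 1e-3
    if not (np.isfinite(mu) and np.isfinite(sigma)):
        raise ValueError(f"non-finite input moments (mu={mu}, sigma={sigma})")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0.0:
        if mu <= params.theta:
            return 0.0
        isi = tau_ref + tau_m * np.log((mu - params.V_r) / (mu - params.theta))
        return 1.0 / isi
    shift = 0.5 * ALPHA * np.sqrt(tau_s / tau_m)
    y_th = (params.theta - mu) / sigma + shift
    y_r = (params.V_r - mu) / sigma + shift
    if y_th > _MAX_BOUND:
        return 0.0
    integral, err = quad(_psi, y_r, y_th, limit=200, epsabs=0.0, epsrel=1e-11)
    if not np.isfinite(integral) or (integral > 0 and err > 1e-6 * abs(integral)):
        raise RuntimeError(f"Siegert quadrature failed: integral={integral}, err={err}")
    return 1.0 / (tau_ref + tau_m * np.sqrt(np.pi) * integral)


def siegert_derivatives(mu: float, sigma: float, params: NeuronParams):
    """Analytic ``(r, dr/dmu, dr/dsigma2)`` of the Siegert rate.

    With ``r = 1/Phi`` and ``Phi = tau_ref + tau_m sqrt(pi) I``,
    ``dI/dmu = (Psi(y_r) - Psi(y_th))/sigma`` and
    ``dI/dsigma = [(theta-mu) ... ]`` via the boundary terms.
    """
    r = siegert_rate(mu, sigma, params)
    if r == 0.0 or sigma == 0.0:
        return r, 0.0, 0.0
    tau_m = params.tau_m * 1e-3
    shift = 0.5 * ALPHA * np.sqrt(params.tau_s / params.tau_m)
    y_th = (params.theta - mu) / sigma + shift
    y_r = (params.V_r - mu) / sigma + shift
    pref = tau_m * np.sqrt(np.pi) * r**2  # -dr = pref * dI
    dI_dmu = (_psi(y_r) - _psi(y_th)) / sigma
    dI_dsigma = ((params.V_r - mu) * _psi(y_r) - (params.theta - mu) * _psi(y_th)) / sigma**2
    dr_dmu = -pref * dI_dmu
    dr_dsigma2 = -pref * dI_dsigma / (2.0 * sigma)
    return r, dr_dmu, dr_dsigma2


def solve_rates(spec: NetworkSpec, r0=None, tol: float = 1e-10) -> WorkingPoint:
    """Self-consistent stationary rates of an LIF network (spikes/s)."""
    if spec.model != "lif":
        raise ValueError("solve_rates requires an lif network")
    tau_m_s = spec.tau_m * 1e-3

    def wp_of(r):
        return working_point_equations(spec, tau_m_s * np.maximum(r, 0.0))

    def gain(r):
        mu, sigma = wp_of(r)
        return np.array(
            [siegert_rate(m, s, p) for m, s, p in zip(mu, sigma, spec.neuron)]
        )

    r = np.full(spec.n_pop, 5.0) if r0 is None else np.asarray(r0, dtype=float)
    trace = []
    for _ in range(2000):
        target = gain(r)
        res = np.max(np.abs(target - r))
        trace.append(res)
        if res < tol:
            break
        r = 0.7 * r + 0.3 * target
    else:
        sol = root(lambda x: gain(x) - x, r, method="hybr")
        if not (sol.success and np.max(np.abs(sol.fun)) < 1e-8):
            raise RuntimeError(
                f"rate self-consistency did not converge; residual trace tail {trace[-5:]}"
            )
        r = np.maximum(sol.x, 0.0)
    mu, sigma = wp_of(r)
    return WorkingPoint(mu=mu, sigma=sigma, activity=r, nu=tau_m_s * r)


def effective_weight(J: float, mu: float, sigma: float, params: NeuronParams, order: int = 1) -> float:
    """Effective (dimensionless) weight of a single synapse of strength ``J``:
    the derivative of the target rate with respect to the source rate.

    A unit source-rate increase shifts the input moments by
    ``dmu = tau_m J`` and ``dsigma2 = tau_m J^2``, so
    ``w = tau_m J dr/dmu`` at linear order, plus ``tau_m J^2 dr/dsigma2``
    at quadratic order (``order=2``).
    """
    _, dr_dmu, dr_ds2 = siegert_derivatives(mu, sigma, params)
    tau_m = params.tau_m * 1e-3
    w = tau_m * J * dr_dmu
    if order >= 2:
        w += tau_m * J**2 * dr_ds2
    elif order != 1:
        raise ValueError("order must be 1 or 2")
    return w


def effective_connectivity_lif(
    spec: NetworkSpec, wp: WorkingPoint, order: int = 1, tau_eff=None
) -> EffectiveConnectivity:
    """``W_ab = w(J_ab; mu_a, sigma_a) K_ab`` from the Siegert-rate slope.

    ``tau_eff`` (ms, per population) sets the time constant of the one-pole
    response kernel; the default uses the membrane time constant.
    """
    npop = spec.n_pop
    w = np.empty((npop, npop))
    for a in range(npop):
        for b in range(npop):
            w[a, b] = effective_weight(spec.J[a, b], wp.mu[a], wp.sigma[a], spec.neuron[a], order)
    tau = spec.tau_m.astype(float) if tau_eff is None else np.asarray(tau_eff, dtype=float)
    return EffectiveConnectivity(W=w * spec.K, S_or_w=w, tau_eff=tau)


def autocovariance_diagonal_lif(spec: NetworkSpec, wp: WorkingPoint) -> np.ndarray:
    """``A = diag(r_alpha / N_alpha)`` in spikes/s per neuron — the
    white (delta-autocovariance) approximation of Poisson-like spiking."""
    return np.diag(wp.activity / spec.N)


# ---------------------------------------------------------------------------
# Spectra and covariances
# ---------------------------------------------------------------------------


def cross_spectrum_lif(
    spec: NetworkSpec,
    wp: WorkingPoint,
    freqs: np.ndarray,
    ec: EffectiveConnectivity | None = None,
):
    """Cross-spectral matrices on an angular-frequency grid (rad/ms).

    Returns ``(C, Cbar)`` where ``Cbar(w) = (1-M)^{-1} A (1-M^T(-w))^{-1}``
    includes the white autocovariance diagonal and ``C = Cbar - A`` separates
    the spike echoes.  Units: A carries spikes/s per neuron, so the spectra
    are in (spikes/s)/neuron-pair; the lag-domain counterpart is recovered
    with frequencies in rad/ms.
    """
    freqs = np.asarray(freqs, dtype=float)
    if ec is None:
        ec = effective_connectivity_lif(spec, wp)
    A = autocovariance_diagonal_lif(spec, wp)
    tau = ec.tau_eff
    npop = spec.n_pop
    eye = np.eye(npop)
    Cb = np.empty((freqs.size, npop, npop), dtype=complex)
    for m, w in enumerate(freqs):
        Mw = transfer_matrix(ec.W, tau, spec.d, w)
        Mmw = transfer_matrix(ec.W, tau, spec.d, -w)
        try:
            left = np.linalg.solve(eye - Mw, A)
            Cb[m] = np.linalg.solve(eye - Mmw, left.T).T
        except np.linalg.LinAlgError as exc:
            raise UnstableNetworkError(
                f"propagator singular at omega = {w:.4f} rad/ms (marginal stability)"
            ) from exc
    C = Cb - A[None, :, :]
    return (
        CovarianceSet(freqs=freqs, C_bar=C, A=A),
        CovarianceSet(freqs=freqs, C_bar=Cb, A=A),
    )


def covariance_time_lif(
    ec: EffectiveConnectivity, A: np.ndarray, tau: float, lags: np.ndarray
) -> CovarianceSet:
    """Spike-train cross-covariance time course for a delay-free LIF network
    with uniform effective time constant ``tau`` (ms).

    ``c(D > 0) = sum_jk [A^jk/tau] [l_j (2-l_j)/(2-l_j-l_k)] u_j u_k^T
    e^{(l_j-1) D/tau}``; negative lags by transposition.  With ``A`` in
    spikes/s per neuron and ``tau`` in ms the result is in
    (spikes/s)*(spikes/ms), i.e. 1e3/s^2; values are returned in 1/s^2.
    """
    lam = _eigen_checks(ec)
    lags = np.asarray(lags, dtype=float)
    Ajk = _mode_amplitudes(ec, A)
    U = ec.right_eigvecs
    npop = ec.n_pop
    coeff = (
        Ajk
        / tau
        * (lam[:, None] * (2.0 - lam[:, None]))
        / (2.0 - lam[:, None] - lam[None, :])
    )
    c = np.empty((lags.size, npop, npop))
    for idx, dt in enumerate(lags):
        D = abs(dt)
        val = np.einsum("jk,aj,bk->ab", coeff * np.exp((lam[:, None] - 1.0) * D / tau), U, U)
        c[idx] = val.real if dt >= 0 else val.real.T
    c *= 1e3  # (spikes/s per neuron) / ms  ->  1/s^2
    return CovarianceSet(lags=lags, c=c, A=A)


def fit_tau_eff(
    lags: np.ndarray,
    c_measured: np.ndarray,
    ec: EffectiveConnectivity,
    A: np.ndarray,
    bounds: tuple[float, float] = (0.2, 40.0),
) -> float:
    """Calibrate the effective response time constant (ms) of the one-pole
    kernel against a measured covariance time course.

    The kernel integral (and hence W) is fixed by the working point; only
    the timescale of the exponential response is free.  In the
    fluctuation-driven regime the fitted value is typically well below the
    membrane time constant.
    """
    from scipy.optimize import minimize_scalar

    lags = np.asarray(lags, dtype=float)
    c_measured = np.asarray(c_measured, dtype=float)

    def loss(tau_eff):
        c = covariance_time_lif(ec, A, tau_eff, lags).c
        return float(((c - c_measured) ** 2).sum())

    res = minimize_scalar(loss, bounds=bounds, method="bounded")
    return float(res.x)


def pole_spectrum(eigenvalues, tau: float, d: float, n_branches: int = 20) -> PoleSet:
    """Poles of the propagator for each eigenvalue of W.

    For ``d > 0`` the poles are ``z_l(lam) = i/tau - (i/d) W_l(lam (d/tau)
    e^{d/tau})`` over Lambert-W branches ``l in [-n_branches, n_branches]``;
    for ``d = 0`` only the principal pole ``z = -i(lam - 1)/tau``.  The
    network is linearly stable iff all poles have ``Im(z) > 0``.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if d < 0:
        raise ValueError("d must be >= 0")
    entries = []
    for j, lam in enumerate(np.atleast_1d(np.asarray(eigenvalues, dtype=complex))):
        for el, z in delayed_poles(lam, tau, d, n_branches):
            entries.append((j, el, z))
    ps = PoleSet(entries=entries)
    for j, el, z in entries:
        lam = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))[j]
        if characteristic_residual(z, lam, tau, d) > 1e-8 * max(1.0, abs(lam)):
            raise RuntimeError(f"pole ({j},{el}) fails the characteristic relation")
    return ps
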