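"""Mean-field theory of recurrent binary networks.

Stationary activities follow from the self-consistency
``<n>_a = erfc((theta_a - mu_a) / (sqrt(2) sigma_a)) / 2`` with the working
point equations closing the loop.  Pairwise averaged covariances follow from
the linearized population dynamics: at zero delay they solve a continuous
Lyapunov equation whose eigenmode solution also yields the full lag course;
with a transmission delay the spectral representation has infinitely many
poles given by branches of the Lambert-W function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root
from scipy.special import erfc, lambertw

from .core import (
    CovarianceSet,
    EffectiveConnectivity,
    NetworkSpec,
    PoleSet,
    WorkingPoint,
    working_point_equations,
)

__all__ = [
    "mean_activity",
    "susceptibility",
    "effective_connectivity_binary",
    "autocovariance_diagonal",
    "zero_lag_covariance",
    "covariance_time_zero_delay",
    "covariance_time_delayed",
    "cross_spectrum_binary",
    "BinaryCovarianceSolution",
    "UnstableNetworkError",
    "DegenerateSpectrumError",
]


class UnstableNetworkError(ValueError):
    """The effective connectivity is outside the linearly stable regime."""


class DegenerateSpectrumError(ValueError):
    """Eigenvalues are degenerate or hit the resonance ``lam_j + lam_k = 2``."""


# ---------------------------------------------------------------------------
# Stationary state
# ---------------------------------------------------------------------------


def _gain(spec: NetworkSpec, n: np.ndarray) -> np.ndarray:
    nc = np.clip(n, 0.0, 1.0)
    mu, sigma = working_point_equations(spec, nc)
    sigma = np.maximum(sigma, 1e-150)
    return 0.5 * erfc((spec.theta - mu) / (np.sqrt(2.0) * sigma))


def mean_activity(
    spec: NetworkSpec,
    x0=None,
    tol: float = 1e-12,
    include_correlation_variance: bool = False,
) -> WorkingPoint:
    """Solve the stationary mean activities of a binary network.

    The fixed point of the erfc gain is found by Newton iterations from a
    coarse grid of starting points (the naive damped iteration diverges for
    strongly coupled networks whose fixed-point map has large negative
    Jacobian eigenvalues).  With ``include_correlation_variance`` the input
    variance additionally includes the pairwise-covariance contribution,
    iterated to self-consistency; the default neglects it, which is accurate
    in the asynchronous regime.
    """
    if spec.model != "binary":
        raise ValueError("mean_activity requires a binary network")
    n = _solve_gain_fixed_point(spec, x0, tol)
    if include_correlation_variance:
        n = _solve_with_correlation_variance(spec, n, tol)
        mu, sigma = _wp_with_correlations(spec, n)
    else:
        mu, sigma = working_point_equations(spec, n)
    if np.any(sigma <= 0):
        raise UnstableNetworkError("input SD collapsed to zero at the solution")
    return WorkingPoint(mu=mu, sigma=sigma, activity=n, nu=n)


def _solve_gain_fixed_point(spec: NetworkSpec, x0, tol) -> np.ndarray:
    npop = spec.n_pop

    def resid(n):
        return _gain(spec, n) - n

    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    vals = (0.02, 0.1, 0.3, 0.5, 0.7, 0.9)
    starts += [np.full(npop, v) for v in vals]
    if npop <= 3:
        starts += [np.array(s) for s in itertools.product(vals, repeat=npop)]
    best = None
    for start in starts:
        sol = root(resid, start, method="hybr")
        res = np.max(np.abs(sol.fun))
        if res < 1e-10 and np.all((sol.x > -1e-9) & (sol.x < 1 + 1e-9)):
            return np.clip(sol.x, 0.0, 1.0)
        if best is None or res < best[0]:
            best = (res, sol.x)
    # damped fallback with small relaxation
    n = np.clip(best[1], 0.0, 1.0) if best is not None else np.full(npop, 0.1)
    for _ in range(100_000):
        target = _gain(spec, n)
        step = np.max(np.abs(target - n))
        n = np.clip(0.95 * n + 0.05 * target, 0.0, 1.0)
        if step < tol:
            return n
    raise RuntimeError(f"mean activity iteration did not converge; residual {step:.3e}")


def _wp_with_correlations(spec: NetworkSpec, n: np.ndarray):
    mu, sigma = working_point_equations(spec, n)
    wp = WorkingPoint(mu=mu, sigma=sigma, activity=n, nu=n)
    ec = effective_connectivity_binary(spec, wp)
    cbar = zero_lag_covariance(ec, autocovariance_diagonal(spec, wp))
    a = n * (1.0 - n)
    c0 = cbar - np.diag(a / spec.N)
    JK = spec.J * spec.K
    corr_var = np.array([(JK[i, :, None] * JK[i, None, :] * c0).sum() for i in range(spec.n_pop)])
    var = sigma**2 + corr_var
    if np.any(var <= 0):
        raise UnstableNetworkError("correlation-corrected input variance non-positive")
    return mu, np.sqrt(var)


def _solve_with_correlation_variance(spec: NetworkSpec, n0, tol):
    def resid(n):
        mu, sigma = _wp_with_correlations(spec, np.clip(n, 1e-9, 1 - 1e-9))
        return 0.5 * erfc((spec.theta - mu) / (np.sqrt(2.0) * sigma)) - n

    sol = root(resid, n0, method="hybr")
    if not sol.success or np.max(np.abs(sol.fun)) > 1e4 * tol:
        raise RuntimeError("correlation-corrected activity solve did not converge")
    return np.clip(sol.x, 0.0, 1.0)


def susceptibility(mu, sigma, theta):
    """Slope of the noise-averaged Heaviside gain: the Gaussian density of the
    input distribution evaluated at threshold."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("susceptibility requires sigma > 0")
    return np.exp(-((mu - theta) ** 2) / (2.0 * sigma**2)) / (np.sqrt(2.0 * np.pi) * sigma)


def effective_connectivity_binary(spec: NetworkSpec, wp: WorkingPoint) -> EffectiveConnectivity:
    """``W_ab = S(mu_a, sigma_a) J_ab K_ab`` with eigen-decomposition."""
    S = susceptibility(wp.mu, wp.sigma, spec.theta)
    W = S[:, None] * spec.J * spec.K
    return EffectiveConnectivity(W=W, S_or_w=S[:, None] * spec.J, tau_eff=spec.tau_m.astype(float))


def autocovariance_diagonal(spec: NetworkSpec, wp: WorkingPoint) -> np.ndarray:
    """Diagonal matrix ``A = diag(a_alpha / N_alpha)`` with
    ``a = <n>(1 - <n>)`` the single-neuron variance."""
    a = wp.activity * (1.0 - wp.activity)
    return np.diag(a / spec.N)


# ---------------------------------------------------------------------------
# Covariances, zero delay
# ---------------------------------------------------------------------------


def _eigen_checks(ec: EffectiveConnectivity):
    ec.require_diagonalizable()
    lam = ec.eigenvalues
    if np.any(lam.real >= 1.0):
        raise UnstableNetworkError(
            f"outside linearly stable regime: max Re(lambda) = {lam.real.max():.4f} >= 1"
        )
    pair_sum = lam[:, None] + lam[None, :]
    if np.any(np.abs(pair_sum - 2.0) < 1e-9):
        raise DegenerateSpectrumError("eigenvalue pair satisfies lambda_j + lambda_k = 2")
    return lam


def _mode_amplitudes(ec: EffectiveConnectivity, A: np.ndarray) -> np.ndarray:
    """``A^{jk} = v_j^T A v_k`` in the biorthogonal eigenbasis."""
    V = ec.left_eigvecs
    return V @ A @ V.T


def zero_lag_covariance(ec: EffectiveConnectivity, A: np.ndarray) -> np.ndarray:
    """Zero-lag covariance matrix (including the ``a/N`` diagonal) from the
    eigenmode solution of the Lyapunov equation
    ``P cbar + (P cbar)^T = 2 A`` with ``P = 1 - W``."""
    lam = _eigen_checks(ec)
    Ajk = _mode_amplitudes(ec, A)
    U = ec.right_eigvecs
    coeff = 2.0 * Ajk / (2.0 - lam[:, None] - lam[None, :])
    cbar = np.einsum("jk,aj,bk->ab", coeff, U, U)
    return cbar.real if np.abs(cbar.imag).max() < 1e-10 * max(np.abs(cbar.real).max(), 1e-300) else cbar


def covariance_time_zero_delay(
    ec: EffectiveConnectivity, A: np.ndarray, tau: float, lags: np.ndarray
) -> CovarianceSet:
    """Cross-covariance time course for a delay-free binary network.

    ``c(D >= 0) = sum_jk [2 A^jk / (2 - l_j - l_k)] u_j u_k^T e^{(l_j-1)D/tau}
    - A e^{-D/tau}``; negative lags follow from ``c(-D) = c(D)^T``.
    """
    lam = _eigen_checks(ec)
    lags = np.asarray(lags, dtype=float)
    Ajk = _mode_amplitudes(ec, A)
    U = ec.right_eigvecs
    coeff = 2.0 * Ajk / (2.0 - lam[:, None] - lam[None, :])
    npop = ec.n_pop
    c = np.empty((lags.size, npop, npop))
    for idx, dt in enumerate(lags):
        D = abs(dt)
        mode = np.einsum("jk,aj,bk->ab", coeff * np.exp((lam[:, None] - 1.0) * D / tau), U, U)
        val = mode.real - A * np.exp(-D / tau)
        c[idx] = val if dt >= 0 else val.T
    a_diag = np.diag(A).copy()
    acov = a_diag[None, :] * np.exp(-np.abs(lags)[:, None] / tau)
    return CovarianceSet(lags=lags, c=c, a=acov, A=A)


# ---------------------------------------------------------------------------
# Delayed networks: Lambert-W poles
# ---------------------------------------------------------------------------


def delayed_poles(lam: complex, tau: float, d: float, n_branches: int) -> list[tuple[int, complex]]:
    """Poles ``z_l = i/tau - (i/d) W_l(lam (d/tau) e^{d/tau})`` of the
    delayed one-pole propagator; for ``d = 0`` only the principal pole
    ``z = -i (lam - 1)/tau`` exists."""
    if d == 0.0:
        return [(0, -1j * (lam - 1.0) / tau)]
    if lam == 0.0:
        # 1/(H^{-1} - 0) = H has its single pole at 1 + i z tau = 0
        return [(0, 1j / tau)]
    arg = lam * (d / tau) * np.exp(d / tau)
    out = []
    for el in range(-n_branches, n_branches + 1):
        z = 1j / tau - (1j / d) * lambertw(arg, k=el)
        out.append((el, complex(z)))
    return out


def characteristic_residual(z: complex, lam: complex, tau: float, d: float) -> float:
    """``|(1 + i z tau) e^{i z d} - lam|`` — zero at a true pole."""
    return abs((1.0 + 1j * z * tau) * np.exp(1j * z * d) - lam)


@dataclass
class BinaryCovarianceSolution:
    """Eigenmode expansion of the delayed covariance.

    ``time_course.c`` holds ``cbar(D)`` (pair-averaged covariance including
    the ``a/N`` diagonal); ``eigen_amplitudes[j, k, l]`` are the mode
    coefficients of ``u_j u_k^T e^{i z_l(lam_j) D}``; ``truncation_error``
    is the magnitude of the largest dropped branch pair.
    """

    eigen_amplitudes: np.ndarray
    poles: PoleSet
    zero_lag: np.ndarray
    time_course: CovarianceSet
    truncation_error: float


def covariance_time_delayed(
    ec: EffectiveConnectivity,
    A: np.ndarray,
    tau: float,
    d: float,
    lags: np.ndarray,
    n_branches: int = 20,
) -> BinaryCovarianceSolution:
    """Covariance time course with a uniform transmission delay.

    Contour integration of the cross-spectrum gives
    ``cbar(D >= 0) = sum_{j,k,l} a_jkl u_j u_k^T e^{i z_l(lam_j) D}`` with
    ``a_jkl = 2 tau i A^{jk} Res_{j,k}[z_l(lam_j)]``.  Branches
    ``l in [-n_branches, n_branches]`` are kept; all retained poles must lie
    in the upper half plane (damped modes).
    """
    lam = _eigen_checks(ec)
    lags = np.asarray(lags, dtype=float)
    if d < 0:
        raise ValueError("delay must be >= 0")
    Ajk = _mode_amplitudes(ec, A)
    U = ec.right_eigvecs
    npop = ec.n_pop
    n_l = 1 if d == 0.0 else 2 * n_branches + 1
    amps = np.zeros((npop, npop, n_l), dtype=complex)
    zs = np.zeros((npop, n_l), dtype=complex)
    entries = []
    trunc = 0.0
    for j in range(npop):
        poles = delayed_poles(lam[j], tau, d, n_branches)
        for li, (el, z) in enumerate(poles):
            if z.imag <= 0:
                raise UnstableNetworkError(
                    f"pole z_{el}(lambda_{j}) = {z:.4f} has Im(z) <= 0: "
                    "unstable or oscillatory network"
                )
            res = _residue_delayed(z, lam[j], lam, tau, d)
            zs[j, li] = z
            entries.append((j, el, z))
            for k in range(npop):
                amps[j, k, li] = 2.0 * tau * 1j * Ajk[j, k] * res[k]
        if len(poles) > 1:
            edge = max(np.abs(amps[j, :, 0]).max(), np.abs(amps[j, :, len(poles) - 1]).max())
            trunc = max(trunc, edge)
    c = np.empty((lags.size, npop, npop))
    for idx, dt in enumerate(lags):
        D = abs(dt)
        val = np.einsum("jkl,jl,aj,bk->ab", amps, np.exp(1j * zs * D), U, U)
        val = val.real
        c[idx] = val if dt >= 0 else val.T
    zero_lag = np.einsum("jkl,aj,bk->ab", amps, U, U).real
    cov = CovarianceSet(lags=lags, c=c, A=A)
    return BinaryCovarianceSolution(
        eigen_amplitudes=amps,
        poles=PoleSet(entries=entries),
        zero_lag=zero_lag,
        time_course=cov,
        truncation_error=trunc,
    )


def _residue_delayed(z, lam_j, lam_all, tau, d):
    """Residue factors of 1/[(H(w)^-1 - l_j)(H(-w)^-1 - l_k)] at z, for all k.

    ``H(w)^-1 = (1 + i w tau) e^{i w d}``; the simple zero at z contributes
    ``1/g'(z)`` with ``g'(z) = i e^{i z d} (tau + d (1 + i z tau))``, and the
    second factor is evaluated at the pole.
    """
    one_iz = 1.0 + 1j * z * tau
    gprime = 1j * np.exp(1j * z * d) * (tau + d * one_iz)
    h_minus_inv = (1.0 - 1j * z * tau) * np.exp(-1j * z * d)
    return 1.0 / (gprime * (h_minus_inv - lam_all))


# ---------------------------------------------------------------------------
# Frequency domain (population-specific time constants and delays)
# ---------------------------------------------------------------------------


def transfer_matrix(W: np.ndarray, tau: np.ndarray, d: np.ndarray, omega: float) -> np.ndarray:
    """``M_ab(w) = H_ab(w) W_ab`` with ``H_ab(w) = e^{-i w d_ab}/(1 + i w tau_a)``."""
    H = np.exp(-1j * omega * d) / (1.0 + 1j * omega * np.asarray(tau)[:, None])
    return H * W


def cross_spectrum_binary(
    spec: NetworkSpec, wp: WorkingPoint, freqs: np.ndarray
) -> CovarianceSet:
    """Pair-averaged cross-spectral matrices ``Cbar(w)`` on an angular
    frequency grid (rad/ms).

    ``Cbar(w) = (1 - M(w))^{-1} D(w) (1 - M(-w)^T)^{-1}`` with the binary
    noise spectrum ``D(w) = diag(2 tau_a a_a / N_a / (1 + w^2 tau_a^2))``.
    """
    freqs = np.asarray(freqs, dtype=float)
    ec = effective_connectivity_binary(spec, wp)
    tau = spec.tau_m.astype(float)
    a = wp.activity * (1.0 - wp.activity)
    An = a / spec.N
    npop = spec.n_pop
    out = np.empty((freqs.size, npop, npop), dtype=complex)
    eye = np.eye(npop)
    for m, w in enumerate(freqs):
        Mw = transfer_matrix(ec.W, tau, spec.d, w)
        Mmw = transfer_matrix(ec.W, tau, spec.d, -w)
        D = np.diag(2.0 * tau * An / (1.0 + w**2 * tau**2))
        try:
            left = np.linalg.solve(eye - Mw, D)
            out[m] = np.linalg.solve(eye - Mmw, left.T).T
        except np.linalg.LinAlgError as exc:
            raise UnstableNetworkError(
                f"propagator singular at omega = {w:.4f} rad/ms (marginal stability)"
            ) from exc
    return CovarianceSet(freqs=freqs, C_bar=out, A=np.diag(An))
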