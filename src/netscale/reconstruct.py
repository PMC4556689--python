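"""Recovering effective connectivity from cross-spectra.

With a known interaction model (delayed one-pole kernels with given time
constants and delays), the pair-averaged cross-spectral matrix determines
the effective connectivity W and the autocovariance diagonal A uniquely —
except in degenerate cases: zero or repeated eigenvalues, vanishing W
entries, or symmetry relations among delays and time constants that allow a
joint rescaling of A and W without changing the spectrum.  The fit operates
on the inverse spectrum, which is a quadratic polynomial in the unknowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import EffectiveConnectivity

__all__ = ["ReconstructionResult", "invert_cross_spectrum", "detect_degeneracy"]


@dataclass
class ReconstructionResult:
    W_hat: np.ndarray
    A_hat: np.ndarray
    residual: np.ndarray
    degenerate: bool = False
    reason: str = ""
    dropped_freqs: list = field(default_factory=list)
    null_direction: np.ndarray | None = None  # direction in (A, W) space along
    # which the fit is unconstrained, when degenerate


def _model_inverse_spectrum(A, W, tau, d, omega):
    """``Cbar^{-1}(w) = (1 - M(-w))^T A^{-1} (1 - M(w))`` with
    ``M_ab(w) = e^{-i w d_ab} W_ab / (1 + i w tau_a)``."""
    eye = np.eye(W.shape[0])
    Hw = np.exp(-1j * omega * d) / (1.0 + 1j * omega * tau[:, None])
    Hmw = np.exp(1j * omega * d) / (1.0 - 1j * omega * tau[:, None])
    Pw = eye - Hw * W
    Pmw = eye - Hmw * W
    return Pmw.T @ np.diag(1.0 / A) @ Pw


def invert_cross_spectrum(
    freqs: np.ndarray,
    C_bar: np.ndarray,
    tau: np.ndarray,
    d: np.ndarray,
    cond_limit: float = 1e12,
) -> ReconstructionResult:
    """Least-squares recovery of (W, A) from sampled cross-spectra.

    ``C_bar[m]`` is the complex spectral matrix at angular frequency
    ``freqs[m]`` (rad/ms); ``tau`` (per population, ms) and ``d`` (delay
    matrix, ms) define the interaction model.  Frequencies at which the
    spectrum is numerically singular are dropped with a warning entry.  The
    fit is exact (residual at machine precision) for noiseless data from a
    non-degenerate network; rank deficiency of the fit is reported as
    degeneracy.
    """
    freqs = np.asarray(freqs, dtype=float)
    C_bar = np.asarray(C_bar, dtype=complex)
    tau = np.asarray(tau, dtype=float)
    d = np.asarray(d, dtype=float)
    npop = C_bar.shape[1]
    if freqs.size < 3:
        raise ValueError("need at least 3 distinct frequencies")
    inv_spectra = []
    used = []
    dropped = []
    for m, w in enumerate(freqs):
        if np.linalg.cond(C_bar[m]) > cond_limit:
            dropped.append(float(w))
            continue
        inv_spectra.append(np.linalg.inv(C_bar[m]))
        used.append(w)
    used = np.asarray(used)
    target = np.asarray(inv_spectra)

    # initialization: A from the high-frequency diagonal (propagator -> 1)
    m_hi = int(np.argmax(np.abs(used)))
    A0 = 1.0 / np.clip(np.real(np.diag(target[m_hi])), 1e-12, None)

    def unpack(x):
        return x[:npop], x[npop:].reshape(npop, npop)

    def resid(x):
        A, W = unpack(x)
        if np.any(A <= 0):
            return np.full(2 * target.size, 1e6)
        out = np.empty((used.size, npop, npop), dtype=complex)
        for m, w in enumerate(used):
            out[m] = _model_inverse_spectrum(A, W, tau, d, w) - target[m]
        return np.concatenate([out.real.ravel(), out.imag.ravel()])

    x0 = np.concatenate([A0, np.zeros(npop * npop)])
    sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    # retry from perturbed starts if stuck in a poor local minimum
    scale = np.abs(target).max()
    if np.max(np.abs(sol.fun)) > 1e-8 * scale:
        rng = np.random.default_rng(0)
        for _ in range(5):
            x0p = x0 * (1 + 0.3 * rng.standard_normal(x0.size))
            x0p[:npop] = np.abs(x0p[:npop])
            trial = least_squares(resid, x0p, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
            if np.max(np.abs(trial.fun)) < np.max(np.abs(sol.fun)):
                sol = trial
            if np.max(np.abs(sol.fun)) < 1e-8 * scale:
                break
    A_hat, W_hat = unpack(sol.x)
    per_freq = resid(sol.x).reshape(2, used.size, npop, npop)
    residual = np.sqrt((per_freq**2).sum(axis=(0, 2, 3)))

    svals, vt = np.linalg.svd(sol.jac)[1:]
    degenerate = bool(svals[-1] < 1e-8 * svals[0])
    reason = ""
    null_direction = None
    if degenerate:
        reason = "rank-deficient fit: a family of (A, W) reproduces the spectrum"
        null_direction = vt[-1]
    else:
        report = detect_degeneracy(EffectiveConnectivity(W=W_hat), tau, d)
        if report["degenerate"]:
            degenerate, reason = True, report["reason"]
    return ReconstructionResult(
        W_hat=W_hat,
        A_hat=A_hat,
        residual=residual,
        degenerate=degenerate,
        reason=reason,
        dropped_freqs=dropped,
        null_direction=null_direction,
    )


def detect_degeneracy(
    ec: EffectiveConnectivity,
    tau: np.ndarray,
    d: np.ndarray,
    zero_tol: float = 1e-6,
    gap_tol: float = 1e-6,
) -> dict:
    """Check the uniqueness preconditions of spectrum-based reconstruction.

    Reports (a) zero or near-zero eigenvalues, (b) repeated eigenvalues,
    (c) the delay/time-constant symmetry ``tau_a = tau_g`` and
    ``d_aa - d_ab = d_ga - d_gb`` for some populations a != g, and
    (d) vanishing entries of W.
    """
    tau = np.asarray(tau, dtype=float)
    d = np.asarray(d, dtype=float)
    lam = ec.eigenvalues
    scale = max(np.abs(lam).max(), 1e-300)
    reasons = []
    if np.any(np.abs(lam) < zero_tol * scale):
        reasons.append("zero eigenvalue")
    n = lam.size
    for j in range(n):
        for k in range(j + 1, n):
            if abs(lam[j] - lam[k]) < gap_tol * scale:
                reasons.append(f"degenerate eigenvalues ({j}, {k})")
    npop = ec.n_pop
    for a in range(npop):
        for g in range(npop):
            if g == a or abs(tau[a] - tau[g]) > 1e-12:
                continue
            for b in range(npop):
                if b == a:
                    continue
                if abs((d[a, a] - d[a, b]) - (d[g, a] - d[g, b])) < 1e-12:
                    reasons.append(
                        f"delay symmetry: tau_{a}=tau_{g}, "
                        f"d[{a},{a}]-d[{a},{b}] = d[{g},{a}]-d[{g},{b}]"
                    )
    Wscale = max(np.abs(ec.W).max(), 1e-300)
    if np.any(np.abs(ec.W) < zero_tol * Wscale):
        reasons.append("vanishing effective-connectivity entries")
    return {"degenerate": bool(reasons), "reason": "; ".join(dict.fromkeys(reasons))}
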