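import numpy as np
import pytest
from scipy.linalg import solve_continuous_lyapunov
from scipy.special import erfc

import netscale as ns
from netscale import binary as bt
from netscale.core import Drive, EffectiveConnectivity, NetworkSpec, NeuronParams
from conftest import random_stable_connectivity


def one_pop(theta=0.0, mu_x=0.0, sigma_x=1.0, J=-1.0, K=100.0):
    return NetworkSpec(
        populations=["x"], N=[1000], K=[[K]], J=[[J]], d=[[0.0]],
        neuron=[NeuronParams(model="binary", tau_m=10, theta=theta)],
        drive=[Drive(kind="gaussian", mu_ext=mu_x, sigma_ext=sigma_x)],
    )


class TestMeanActivity:
    def test_threshold_at_drive_mean_gives_half(self):
        spec = one_pop(theta=2.0, mu_x=2.0, sigma_x=1.0, J=0.0, K=0.0)
        wp = ns.mean_activity(spec)
        assert wp.activity[0] == pytest.approx(0.5, abs=1e-12)

    def test_asymmetric_network_self_consistency(self, asym_binary, asym_wp):
        # the solution satisfies the erfc gain equation to solver tolerance
        n = asym_wp.activity
        target = 0.5 * erfc(
            (asym_binary.theta - asym_wp.mu) / (np.sqrt(2) * asym_wp.sigma)
        )
        np.testing.assert_allclose(n, target, atol=1e-9)
        # mean-field activities of the strongly coupled two-population network
        assert n[0] == pytest.approx(0.147, abs=0.002)
        assert n[1] == pytest.approx(0.070, abs=0.002)

    def test_symmetric_network_activity(self, sym_binary):
        wp = ns.mean_activity(sym_binary)
        assert wp.activity[0] == pytest.approx(wp.activity[1], rel=1e-10)
        assert 0.2 < wp.activity[0] < 0.35

    def test_correlation_variance_switch_moves_activity_down(self, sym_binary):
        plain = ns.mean_activity(sym_binary).activity
        corr = ns.mean_activity(sym_binary, include_correlation_variance=True).activity
        assert corr[0] != plain[0]
        assert abs(corr[0] - plain[0]) < 0.02


class TestSusceptibility:
    def test_gaussian_peak_value(self):
        assert ns.susceptibility(0.0, 1.0, 0.0) == pytest.approx(0.3989422804, abs=1e-9)

    @pytest.mark.parametrize("x", [0.3, 1.0, 2.5])
    def test_symmetric_about_threshold(self, x):
        theta = 1.2
        assert ns.susceptibility(theta + x, 2.0, theta) == pytest.approx(
            ns.susceptibility(theta - x, 2.0, theta), rel=1e-14
        )

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            ns.susceptibility(0.0, 0.0, 0.0)


class TestEffectiveConnectivity:
    def test_zero_weights_give_zero_matrix(self):
        spec = one_pop(J=0.0)
        wp = ns.mean_activity(spec)
        ec = ns.effective_connectivity_binary(spec, wp)
        assert np.all(ec.W == 0)

    def test_symmetric_structure_and_eigenvalues(self, sym_binary):
        wp = ns.mean_activity(sym_binary)
        ec = ns.effective_connectivity_binary(sym_binary, wp)
        We = ec.W[0, 0]
        gamma_g = 3.0  # gamma=1, g=3
        np.testing.assert_allclose(ec.W, We * np.array([[1, -gamma_g], [1, -gamma_g]]), rtol=1e-12)
        lam = sorted(ec.eigenvalues.real)
        assert lam[1] == pytest.approx(0.0, abs=1e-12)
        assert lam[0] == pytest.approx(We * (1 - gamma_g), rel=1e-12)

    def test_eigendecomposition_matches_numpy(self, asym_binary, asym_wp):
        ec = ns.effective_connectivity_binary(asym_binary, asym_wp)
        S = ns.susceptibility(asym_wp.mu, asym_wp.sigma, asym_binary.theta)
        W_indep = S[:, None] * asym_binary.J * asym_binary.K
        np.testing.assert_allclose(
            sorted(ec.eigenvalues.real), sorted(np.linalg.eigvals(W_indep).real), rtol=1e-12
        )
        # biorthogonality v_j . u_k = delta_jk
        np.testing.assert_allclose(
            ec.left_eigvecs @ ec.right_eigvecs, np.eye(2), atol=1e-12
        )


class TestZeroLagCovariance:
    def test_uncoupled_returns_diagonal(self):
        ec = EffectiveConnectivity(W=np.zeros((2, 2)))
        A = np.diag([0.3, 0.7])
        np.testing.assert_allclose(ns.zero_lag_covariance(ec, A), A, atol=1e-15)

    def test_one_population_closed_form(self):
        W = -3.0
        aN = 0.21 / 1000
        cbar = ns.zero_lag_covariance(EffectiveConnectivity(W=[[W]]), np.array([[aN]]))
        assert cbar[0, 0] == pytest.approx(aN / (1 - W), rel=1e-12)
        # cross-covariance part satisfies (1-W) c(0) = W a / N
        c0 = cbar[0, 0] - aN
        assert (1 - W) * c0 == pytest.approx(W * aN, rel=1e-12)

    def test_matches_generic_lyapunov_solver(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            W = random_stable_connectivity(rng, 3)
            A = np.diag(rng.uniform(0.2, 2.0, 3))
            ec = EffectiveConnectivity(W=W)
            cbar = ns.zero_lag_covariance(ec, A)
            oracle = solve_continuous_lyapunov(np.eye(3) - W, 2 * A)
            np.testing.assert_allclose(cbar, oracle, atol=1e-10)

    def test_lyapunov_residual_below_tolerance(self, asym_binary, asym_wp):
        ec = ns.effective_connectivity_binary(asym_binary, asym_wp)
        A = bt.autocovariance_diagonal(asym_binary, asym_wp)
        cbar = ns.zero_lag_covariance(ec, A)
        P = np.eye(2) - ec.W
        resid = np.abs(P @ cbar + (P @ cbar).T - 2 * A).max()
        assert resid < 1e-10

    def test_unstable_network_rejected(self):
        ec = EffectiveConnectivity(W=[[1.5]])
        with pytest.raises(bt.UnstableNetworkError, match="stable"):
            ns.zero_lag_covariance(ec, np.array([[1.0]]))

    def test_inhibitory_feedback_suppresses_correlations(self):
        """More negative feedback decreases |c(0)| = |W| a / (N(1-W))... the
        cross-covariance magnitude relative to a/N shrinks towards -a/N/2."""
        aN = 1e-3
        values = []
        for W in (-0.5, -2.0, -8.0):
            cbar = ns.zero_lag_covariance(EffectiveConnectivity(W=[[W]]), np.array([[aN]]))
            values.append(cbar[0, 0] - aN)  # c(0) = W aN/(1-W) < 0
        assert values[0] > values[1] > values[2] > -aN

    def test_one_over_n_scaling_exact(self):
        rng = np.random.default_rng(1)
        W = random_stable_connectivity(rng, 3)
        a = rng.uniform(0.1, 0.25, 3)
        N = np.array([500.0, 800.0, 300.0])
        ec = EffectiveConnectivity(W=W)
        c1 = ns.zero_lag_covariance(ec, np.diag(a / N))
        c2 = ns.zero_lag_covariance(ec, np.diag(a / (2 * N)))
        np.testing.assert_allclose(c2, 0.5 * c1, rtol=1e-12)


class TestCovarianceTimeCourse:
    def test_uncoupled_cross_covariance_vanishes(self):
        ec = EffectiveConnectivity(W=np.zeros((2, 2)))
        A = np.diag([0.3, 0.7])
        cov = bt.covariance_time_zero_delay(ec, A, 10.0, np.linspace(0, 40, 9))
        assert np.abs(cov.c).max() < 1e-14

    def test_one_population_closed_form_lag_course(self):
        W, tau, aN = -2.0, 10.0, 3e-4
        lags = np.linspace(0, 50, 11)
        cov = bt.covariance_time_zero_delay(
            EffectiveConnectivity(W=[[W]]), np.array([[aN]]), tau, lags
        )
        expected = aN / (1 - W) * np.exp((W - 1) / tau * lags) - aN * np.exp(-lags / tau)
        np.testing.assert_allclose(cov.c[:, 0, 0], expected, rtol=1e-12)

    def test_symmetry_under_lag_reversal(self, asym_binary, asym_wp):
        ec = ns.effective_connectivity_binary(asym_binary, asym_wp)
        A = bt.autocovariance_diagonal(asym_binary, asym_wp)
        lags = np.array([-7.0, 7.0])
        cov = bt.covariance_time_zero_delay(ec, A, 10.0, lags)
        np.testing.assert_allclose(cov.c[0], cov.c[1].T, rtol=1e-12)

    def test_delayed_solution_recovers_zero_delay_limit(self):
        rng = np.random.default_rng(5)
        W = random_stable_connectivity(rng, 3)
        A = np.diag(rng.uniform(0.2, 1.0, 3))
        ec = EffectiveConnectivity(W=W)
        tau = 10.0
        lags = np.linspace(0, 40, 21)
        ref = bt.covariance_time_zero_delay(ec, A, tau, lags)
        sol = bt.covariance_time_delayed(ec, A, tau, 1e-7, lags, n_branches=2)
        acov = A[None] * np.exp(-lags / tau)[:, None, None]
        np.testing.assert_allclose(
            sol.time_course.c - acov, ref.c,
            atol=1e-6 * np.abs(ref.c).max(),
        )

    def test_poles_satisfy_characteristic_equation(self):
        tau, d = 10.0, 1.0
        for lam in (-5.0, -0.5 + 0.3j, 0.8):
            for _, z in bt.delayed_poles(lam, tau, d, 8):
                assert bt.characteristic_residual(z, lam, tau, d) < 1e-8

    def test_small_delay_close_to_zero_delay(self, asym_binary, asym_wp):
        """With d = 0.1 ms << tau the delayed covariance is well approximated
        by the delay-free solution."""
        ec = ns.effective_connectivity_binary(asym_binary, asym_wp)
        A = bt.autocovariance_diagonal(asym_binary, asym_wp)
        lags = np.linspace(0, 30, 16)
        sol = bt.covariance_time_delayed(ec, A, 10.0, 0.1, lags, n_branches=20)
        ref = bt.covariance_time_zero_delay(ec, A, 10.0, lags)
        acov = A[None] * np.exp(-lags / 10.0)[:, None, None]
        err = np.abs(sol.time_course.c - acov - ref.c).max()
        assert err < 0.1 * np.abs(ref.c).max()

    def test_reconstructed_covariance_is_real(self, sym_binary):
        wp = ns.mean_activity(sym_binary)
        ec = ns.effective_connectivity_binary(sym_binary, wp)
        A = bt.autocovariance_diagonal(sym_binary, wp)
        sol = bt.covariance_time_delayed(ec, A, 10.0, 0.1, np.linspace(0, 20, 6))
        amps = sol.eigen_amplitudes
        recon = np.einsum("jkl,aj,bk->ab", amps, ec.right_eigvecs, ec.right_eigvecs)
        # residual imaginary parts shrink with the branch cutoff (~l^-3);
        # at the default truncation they sit well below 1e-7 of the signal
        assert np.abs(recon.imag).max() < 1e-7 * max(np.abs(recon.real).max(), 1e-300)
        assert sol.truncation_error < 1e-2 * np.abs(recon.real).max()


class TestCrossSpectrum:
    def test_uncoupled_gives_lorentzian_diagonal(self):
        spec = one_pop(J=0.0, K=0.0, sigma_x=1.0, theta=0.0)
        wp = ns.mean_activity(spec)
        freqs = np.array([0.0, 0.3, 1.0])
        cs = ns.cross_spectrum_binary(spec, wp, freqs)
        a = wp.activity[0] * (1 - wp.activity[0])
        tau = 10.0
        expected = 2 * tau * a / spec.N[0] / (1 + freqs**2 * tau**2)
        np.testing.assert_allclose(cs.C_bar[:, 0, 0].real, expected, rtol=1e-12)
        assert np.abs(cs.C_bar[:, 0, 0].imag).max() < 1e-15

    def test_reality_condition(self, asym_binary, asym_wp):
        freqs = np.array([0.4, -0.4])
        cs = ns.cross_spectrum_binary(asym_binary, asym_wp, freqs)
        np.testing.assert_allclose(cs.C_bar[0], np.conj(cs.C_bar[1]), rtol=1e-12)

    def test_inverse_fft_matches_pole_expansion(self, asym_binary, asym_wp):
        """Fourier inversion of the spectral matrix (with the analytically
        transformable noise term handled in closed form) reproduces the
        Lambert-W pole expansion of the lag course."""
        ec = ns.effective_connectivity_binary(asym_binary, asym_wp)
        A = bt.autocovariance_diagonal(asym_binary, asym_wp)
        tau, d = 10.0, 0.1
        n, dt = 2**15, 0.02
        freqs = 2 * np.pi * np.fft.fftfreq(n, dt)
        cs = ns.cross_spectrum_binary(asym_binary, asym_wp, freqs)
        D = np.zeros((n, 2, 2))
        for p in range(2):
            D[:, p, p] = 2 * tau * A[p, p] / (1 + freqs**2 * tau**2)
        lag_grid = np.arange(n) * dt
        rest = np.fft.ifft(cs.C_bar - D, axis=0).real / dt
        cbar_fft = rest + A[None] * np.exp(-lag_grid / tau)[:, None, None]
        sel = lag_grid <= 20
        sol = bt.covariance_time_delayed(ec, A, tau, d, lag_grid[sel], n_branches=30)
        err = np.abs(cbar_fft[sel] - sol.time_course.c).max()
        assert err < 1e-4 * np.abs(sol.time_course.c).max()
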