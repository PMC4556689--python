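import numpy as np
import pytest

import netscale as ns
from netscale import binary as bt
from netscale import lif as lt
from netscale.core import Drive, NetworkSpec, NeuronParams
from netscale.simulate import SimulationOutput, build_connectivity
from conftest import small_lif_pair


class TestConnectivity:
    def test_fixed_indegree_no_multapses_no_autapses(self, sym_binary):
        indptr, targets = build_connectivity(sym_binary, seed=0)
        N = int(sym_binary.N.sum())
        in_deg = np.zeros(N, dtype=int)
        for s in range(N):
            row = targets[indptr[s] : indptr[s + 1]]
            assert s not in row  # no autapses
            assert len(np.unique(row)) == len(row)  # no multapses per source
            for t in row:
                in_deg[t] += 1
        # every neuron receives K + gamma*K = 400 synapses
        assert np.all(in_deg == 400)

    def test_same_seed_same_wiring(self, sym_binary):
        a = build_connectivity(sym_binary, seed=5)
        b = build_connectivity(sym_binary, seed=5)
        assert np.array_equal(a[1], b[1])
        c = build_connectivity(sym_binary, seed=6)
        assert not np.array_equal(a[1], c[1])


class TestBinarySimulator:
    def test_silent_neuron_stays_silent(self):
        spec = NetworkSpec(
            populations=["x"], N=[1], K=[[0.0]], J=[[0.0]], d=[[0.0]],
            neuron=[NeuronParams(model="binary", tau_m=10, theta=1.0)],
            drive=[Drive(kind="dc", I_dc=0.0)],
        )
        run = ns.simulate_binary(spec, T=500.0, seed=1)
        assert run.mean_activity[0] == 0.0
        assert run.states.max() == 0

    def test_same_seed_bit_identical(self, sym_binary):
        r1 = ns.simulate_binary(sym_binary, T=500.0, seed=9, init_active_fraction=0.3)
        r2 = ns.simulate_binary(sym_binary, T=500.0, seed=9, init_active_fraction=0.3)
        assert np.array_equal(r1.states, r2.states)
        np.testing.assert_array_equal(r1.mean_activity, r2.mean_activity)

    def test_symmetric_network_mean_matches_theory(self, sym_binary):
        """Simulated mean activity agrees with the correlation-corrected
        mean-field solve within 3 SEM (and the plain solve within 2.5%)."""
        run = ns.simulate_binary(sym_binary, T=12000.0, seed=3,
                                 init_active_fraction=0.27,
                                 record_ids=np.empty(0, dtype=np.int64))
        # SEM from block means of population counts
        counts = run.pop_counts[int(500 / run.dt):]
        blocks = np.array_split(counts / sym_binary.N[None, :], 10)
        bm = np.array([b.mean(axis=0) for b in blocks])
        sem = bm.std(axis=0, ddof=1) / np.sqrt(len(bm))
        corr = ns.mean_activity(sym_binary, include_correlation_variance=True).activity
        plain = ns.mean_activity(sym_binary).activity
        assert np.all(np.abs(run.mean_activity - corr) < 3 * sem + 1e-3)
        np.testing.assert_allclose(run.mean_activity, plain, rtol=0.04)

    def test_shared_stream_identity_of_weight_scalings(self):
        """With in-degrees reduced to kappa, the J ~ 1/K + variance-adjusted
        drive and the J ~ 1/sqrt(K) + rescaled drive networks have all
        internal inputs and thresholds scaled by a common factor, so shared
        random streams give bit-identical state trajectories."""
        base = NetworkSpec(
            populations=["e", "i"], N=[500, 500],
            K=[[50.0, 100.0], [150.0, 200.0]], J=[[3.0, -5.0], [3.0, -6.0]],
            d=np.full((2, 2), 0.1),
            neuron=[NeuronParams(model="binary", tau_m=10, theta=0)] * 2,
            drive=[Drive(kind="gaussian", mu_ext=50, sigma_ext=60),
                   Drive(kind="gaussian", mu_ext=40, sigma_ext=50)],
        )
        wp = ns.mean_activity(base)
        kap = 0.75
        s2C = ns.binary_generic_scaling_drive(base, wp, kap, 1 / kap)
        specC = base.copy()
        specC.K = kap * base.K
        specC.J = base.J / kap
        specC.drive = [Drive(kind="gaussian", mu_ext=dr.mu_ext, sigma_ext=float(np.sqrt(v)))
                       for dr, v in zip(base.drive, s2C)]
        s2D = ns.binary_generic_scaling_drive(base, wp, kap, 1 / np.sqrt(kap))
        specD = base.copy()
        specD.K = kap * base.K
        specD.J = base.J / np.sqrt(kap)
        specD.drive = [Drive(kind="gaussian", mu_ext=float(np.sqrt(kap) * dr.mu_ext),
                             sigma_ext=float(np.sqrt(v)))
                       for dr, v in zip(base.drive, s2D)]
        runC = ns.simulate_binary(specC, T=1500.0, seed=7)
        runD = ns.simulate_binary(specD, T=1500.0, seed=7)
        assert np.array_equal(runC.states, runD.states)

    def test_asymmetric_covariances_match_theory_within_sem(self, asym_binary, asym_wp):
        """Population-averaged cross-covariances from a direct simulation
        agree with the linear-response prediction within sampling error."""
        rec = np.concatenate([np.arange(0, 1600), np.arange(5000, 6600)])
        run = ns.simulate_binary(asym_binary, T=8000.0, seed=21, record_ids=rec)
        mc = ns.measure_covariances(run, bin=0.3, max_lag=11.0)
        ec = ns.effective_connectivity_binary(asym_binary, asym_wp)
        A = bt.autocovariance_diagonal(asym_binary, asym_wp)
        sol = bt.covariance_time_delayed(ec, A, 10.0, 0.1, mc.lags, n_branches=20)
        acov = A[None] * np.exp(-np.abs(mc.lags) / 10.0)[:, None, None]
        c_theory = sol.time_course.c - acov
        for D in (0.0, 5.0, 10.0):
            idx = int(np.argmin(np.abs(mc.lags - D)))
            assert np.all(np.abs(c_theory[idx] - mc.c_hat[idx]) < 4.0 * mc.sem[idx])


class TestLifSimulator:
    def test_no_input_no_spikes(self, lif_neuron):
        spec = NetworkSpec(
            populations=["x"], N=[1], K=[[0.0]], J=[[0.0]], d=[[1.0]],
            neuron=[lif_neuron], drive=[Drive(kind="dc", I_dc=0.0)],
        )
        run = ns.simulate_lif(spec, T=1000.0, dt=0.1, seed=1)
        assert run.spike_counts.sum() == 0

    def test_deterministic_suprathreshold_isi(self, lif_neuron):
        spec = NetworkSpec(
            populations=["x"], N=[1], K=[[0.0]], J=[[0.0]], d=[[1.0]],
            neuron=[lif_neuron], drive=[Drive(kind="dc", I_dc=30.0)],
        )
        run = ns.simulate_lif(spec, T=10000.0, dt=0.01, seed=1, burn_in=100.0)
        assert run.rates[0] == pytest.approx(1000.0 / (2 + 20 * np.log(2)), rel=0.005)

    def test_delay_smaller_than_dt_rejected(self, lif_neuron):
        spec = NetworkSpec(
            populations=["x"], N=[2], K=[[1.0]], J=[[0.1]], d=[[0.05]],
            neuron=[lif_neuron], drive=[Drive(kind="dc", I_dc=0.0)],
        )
        with pytest.raises(ValueError, match="time step"):
            ns.simulate_lif(spec, T=100.0, dt=0.1, seed=0)

    def test_same_seed_bit_identical(self):
        spec = small_lif_pair()
        r1 = ns.simulate_lif(spec, T=500.0, dt=0.1, seed=4)
        r2 = ns.simulate_lif(spec, T=500.0, dt=0.1, seed=4)
        np.testing.assert_array_equal(r1.spikes, r2.spikes)

    def test_network_rates_track_siegert_solve(self):
        """Simulated rates stay within 5% of the self-consistent Siegert
        rates in the fluctuation-driven regime."""
        spec = small_lif_pair()
        wp = ns.solve_rates(spec)
        run = ns.simulate_lif(spec, T=6000.0, dt=0.1, seed=5, burn_in=500.0,
                              record="counts")
        np.testing.assert_allclose(run.rates, wp.activity, rtol=0.05)

    def test_single_neuron_rate_grid_vs_siegert(self, lif_neuron):
        """Isolated neurons under balanced Poisson drive across working
        points: grid simulation within 5% of the Siegert formula."""
        for mu, sigma in ((15.0, 10.0), (12.0, 8.0)):
            spec = NetworkSpec(
                populations=["x"], N=[300], K=[[0.0]], J=[[0.0]], d=[[1.0]],
                neuron=[lif_neuron],
                drive=[Drive(kind="gaussian", mu_ext=mu, sigma_ext=sigma, J_ext=0.2)],
            )
            run = ns.simulate_lif(spec, T=20000.0, dt=0.1, seed=11, burn_in=500.0,
                                  record="counts")
            assert run.rates[0] == pytest.approx(
                ns.siegert_rate(mu, sigma, lif_neuron), rel=0.05
            )


class TestMeasureCovariances:
    def test_independent_poisson_pairs_uncorrelated(self):
        rng = np.random.default_rng(0)
        N, T, rate = 1000, 20000.0, 20.0
        spikes = []
        for j in range(N):
            n = rng.poisson(rate * T * 1e-3)
            spikes.append(np.column_stack([np.full(n, j, float),
                                           np.sort(rng.uniform(0, T, n))]))
        spikes = np.vstack(spikes)
        out = SimulationOutput(
            kind="spike_trains", T=T, dt=0.1, seed=0, spec_hash="synthetic",
            pop_sizes=np.array([N // 2, N // 2]),
            pop_of=np.repeat([0, 1], N // 2), burn_in=0.0, spikes=spikes,
            spike_counts=np.bincount(spikes[:, 0].astype(int), minlength=N),
        )
        mc = ns.measure_covariances(out, bin=0.5, max_lag=10.0)
        # analytic noise floor: group-mean signals have variance
        # (rate/bin)/G, and each lag averages n_bins largely independent
        # products; 5 standard errors bounds every entry
        n_bins = int(T / 0.5)
        noise = (rate / 0.5e-3) / (N // 4) / np.sqrt(n_bins)
        assert np.abs(mc.c_hat).max() < 5.0 * noise
        assert abs(mc.c_hat.mean()) < noise
        # autocovariance away from zero lag also vanishes
        off = np.abs(mc.lags) > 1.0
        assert np.abs(mc.a_hat[off]).max() < 0.05 * mc.a_hat.max()

    def test_estimator_symmetry_exact(self):
        spec = small_lif_pair()
        run = ns.simulate_lif(spec, T=3000.0, dt=0.1, seed=2)
        mc = ns.measure_covariances(run, bin=0.5, max_lag=8.0)
        np.testing.assert_array_equal(mc.c_hat[:, 0, 1], mc.c_hat[::-1, 1, 0])

    def test_lif_integrated_covariance_matches_propagator(self):
        """Zero-frequency (integrated) covariances depend only on W and the
        noise diagonal.  Using the measured autocovariance integral for the
        noise amplitude, the propagator prediction reproduces the simulated
        integrals (the white r/N approximation overestimates them because
        refractoriness makes the spike trains sub-Poissonian)."""
        spec = small_lif_pair()
        wp = ns.solve_rates(spec)
        spec0 = spec.copy()
        spec0.d[:] = 0.0
        ec = lt.effective_connectivity_lif(spec0, wp)
        run = ns.simulate_lif(spec, T=20000.0, dt=0.1, seed=5, burn_in=500.0)
        mc = ns.measure_covariances(run, bin=0.5, max_lag=20.0, n_auto=150)
        a_int = mc.a_hat.sum(axis=0) * mc.bin * 1e-3  # r * Fano
        assert np.all(a_int < run.rates)  # sub-Poissonian
        A_eff = np.diag(a_int / spec.N)
        eye = np.eye(2)
        pred = np.linalg.solve(eye - ec.W, A_eff) @ np.linalg.inv(eye - ec.W.T) - A_eff
        measured = mc.c_hat.sum(axis=0) * mc.bin * 1e-3
        np.testing.assert_allclose(measured, pred, rtol=0.4)
        # sign structure: ee and ei positive, ii negative for this network
        assert measured[0, 0] > 0 and pred[0, 0] > 0
        assert measured[1, 1] < 0 and pred[1, 1] < 0
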