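# netscale

Mean-field correlations and scaling limits of recurrent binary and leaky
integrate-and-fire (LIF) networks.

Network models of cortical circuits are routinely downscaled — fewer neurons
(N), fewer synapses per neuron (the in-degree K) — to fit on available
hardware. First-order statistics (mean activities or firing rates) are easy
to preserve by adjusting weights and drive. This package implements the
second-order story: the temporal structure of *pairwise averaged activity
covariances* is in one-to-one correspondence with the population-level
**effective connectivity**

    W_ab = S(mu_a, sigma_a) * J_ab * K_ab ,

the susceptibility S of the target population times synaptic weight times
in-degree. Any downscaling that preserves covariances must therefore
preserve W — forcing J ∝ 1/K with a compensating *reduction* of the
external input variance, which is possible only down to

    kappa_min = sigma_int^2 / (sigma_int^2 + sigma_ext^2) ,

the ratio of internally generated to total input variance. Below this
in-degree factor, no drive can restore the working point, and the network is
irreducible at second order.

The package is aimed at computational neuroscientists who downscale network
models (or infer connectivity from correlations) and want the bias and the
feasibility limits quantified. It provides:

* **core** — network configs (YAML schema `netscale-spec v1`), working-point
  equations, effective-connectivity containers;
* **binary** — erfc-gain mean activities (with optional correlation
  correction to the input variance), susceptibility, zero-lag covariances via
  the Lyapunov eigenmode solution, covariance time courses for delayed
  networks via Lambert-W pole expansions, cross-spectra;
* **lif** — Siegert firing rates (boundary-shifted for synaptic filtering),
  self-consistent rate solves, effective synaptic weights to quadratic
  order, cross-spectra, delay-free covariance time courses, propagator pole
  spectra (stability/Hopf analysis);
* **scaling** — the kappa_min limit, J ∝ 1/K downscaling with balanced
  Poisson + DC drive adjustment, the generic binary (kappa, iota) drive
  formula, zero-lag-preserving scaling of symmetric binary networks, and the
  degenerate (zero-eigenvalue) scaling of symmetric spiking networks;
* **simulate** — event-driven binary and clock-driven LIF reference
  simulators (numba) with fixed in-degree, multapse- and autapse-free
  connectivity, plus disjoint-group covariance estimation;
* **reconstruct** — recovery of (W, A) from sampled cross-spectra, with
  explicit detection of the degenerate cases where the mapping is not
  one-to-one.

## Worked example

```python
import numpy as np
import netscale as ns

spec = ns.example_spec("asymmetric_binary")   # two populations, 10,000 neurons
wp = ns.mean_activity(spec)
per_pop, kappa_min = ns.min_kappa(spec, wp)
print("mean activities:", np.round(wp.activity, 4))
print("kappa_min per population:", np.round(per_pop, 3), "-> limit", round(kappa_min, 3))

ec = ns.effective_connectivity_binary(spec, wp)
print("effective connectivity:\n", np.round(ec.W, 2))
print("eigenvalues:", np.round(ec.eigenvalues.real, 2))
```

prints

```
mean activities: [0.1472 0.0701]
kappa_min per population: [0.379 0.719] -> limit 0.719
effective connectivity:
 [[  4.54 -15.12]
 [  6.42 -17.11]]
eigenvalues: [ -1.8  -10.77]
```

The excitatory population is active 14.7% of the time and the inhibitory one
7.0% (a direct simulation gives 0.155/0.072; the gap is the correlation
contribution to the input variance, recovered by
`mean_activity(spec, include_correlation_variance=True)`). The binding
population for downscaling is the inhibitory one: in-degrees can be reduced
to 72% of their natural value, and no further, before the required external
variance turns negative. Both eigenvalues of W are far in the stable region
(real part < 1), so the zero-lag covariances follow from
`ns.zero_lag_covariance(ec, A)` and the full lag course from
`ns.covariance_time_delayed(...)`.

A command-line interface mirrors the library:

```
netscale theory binary --spec net.yaml --lags 0:50:0.1 --out cov.h5
netscale simulate --spec net.yaml -T 30000 --seed 42 --out run.h5
netscale scale jk --spec net.yaml --kappa 0.75 --out scaled.yaml
netscale reconstruct --cov cov.h5 --tau 20,10 --delays d.yaml --out W.json
```

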