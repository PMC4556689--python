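# Models and methods

## Network models

**Binary networks.** Each neuron carries a state n ∈ {0, 1} and is updated
at independent Poisson times with rate 1/τ (τ in ms). On update, the new
state is Θ(Σ_k J_k n_k + x − θ) with a Heaviside gain Θ, threshold θ, and an
external sample x drawn fresh at every update event from a Gaussian with
population-specific mean and SD. Connectivity has fixed in-degrees K_ab
(synapses per target in population a from population b), no multapses and
no autapses.

**LIF networks.** Leaky integrate-and-fire neurons with exponential
current-based synapses: τ_m dV/dt = −V + I, τ_s dI/dt = −I + τ_m Σ J s(t−d),
threshold θ, reset V_r, absolute refractory period τ_ref. External drive is
a balanced pair of Poisson trains (weights ±J_ext) plus a DC current; a
Gaussian drive specification (μ_ext, σ_ext) is realized by the equivalent
balanced Poisson drive under the diffusion approximation.

## Stationary state

The working point (μ_a, σ_a) of each population is the mean and SD of its
summed synaptic input: μ_a = Σ_b J_ab K_ab ν_b + μ_ext,a and
σ_a² = Σ_b J_ab² K_ab φ_b + σ²_ext,a, with the dimensionless activity
ν = ⟨n⟩ (binary) or ν = τ_m r (spiking, τ_m in seconds, r in spikes/s), and
φ = ν(1−ν) for binary neurons or φ = ν for Poisson-like spiking
(refractoriness neglected). Binary mean activities solve
⟨n⟩ = ½ erfc((θ−μ)/(√2 σ)) self-consistently; LIF rates solve the Siegert
mean-first-passage formula with integration boundaries shifted by
(α/2)√(τ_s/τ_m), α = √2·|ζ(½)|, to first order in the synaptic filtering
time.

*Solver.* The binary self-consistency is solved by Newton iterations
(scipy `root`/hybr) from a coarse grid of starting points. A naively damped
fixed-point iteration is **not** used: for strongly coupled networks the
fixed-point map has large negative Jacobian eigenvalues (≈ −10 for the
bundled asymmetric example), so any relaxation ≳ 0.2 oscillates and
diverges, and greedy adaptive damping stalls in a spurious residual
minimum. Multi-starting also surfaces multistability when present; the
solver returns the first root found in a deterministic scan order and
accepts an explicit initial guess. LIF rates use damped iteration
(relaxation 0.3) with a Newton fallback.

*Correlation correction.* The diffusion approximation ignores the
contribution of pairwise covariances to the input variance. The optional
switch `mean_activity(..., include_correlation_variance=True)` adds
Σ J J K K c(0) self-consistently (covariances from the Lyapunov solution).
For the asymmetric example this moves the excitatory activity from 0.147 to
0.155, in agreement with direct simulation to ~1e−3. The switch is off by
default because the plain diffusion form is the standard reference point.

## Covariances

With the linearized effective connectivity W_ab = S(μ_a, σ_a) J_ab K_ab
(binary susceptibility S = Gaussian density of the input distribution at
threshold) or W_ab = w(J_ab) K_ab (LIF, w the derivative of the Siegert
rate with respect to a source rate), the pair-averaged zero-lag covariance
matrix solves the continuous Lyapunov equation P c̄ + (P c̄)ᵀ = 2A with
P = 1 − W and the noise diagonal A = diag(a/N) (binary single-neuron
variance a = ⟨n⟩(1−⟨n⟩)) or diag(r/N) (white spike-train approximation).
The implementation uses the biorthogonal eigenmode sum
c̄ = Σ_jk 2A^jk/(2−λ_j−λ_k) u_j u_kᵀ and is checked against
`scipy.linalg.solve_continuous_lyapunov` in the tests. Lag courses are
eigenmode sums of exponentials e^{(λ_j−1)Δ/τ}; for a uniform transmission
delay d the spectrum of the delayed one-pole propagator has infinitely many
poles z_l(λ) = i/τ − (i/d)·W_l(λ (d/τ) e^{d/τ}) over Lambert-W branches l,
and the covariance is the corresponding residue sum. Branches are truncated
at |l| ≤ 20 by default; the magnitude of the outermost retained amplitude
is reported as a truncation diagnostic (residual imaginary parts decay
roughly as the cube of the cutoff). A zero eigenvalue contributes only its
principal pole z = i/τ. Population-specific time constants and delays are
handled in the frequency domain (no closed-form back-transform is
attempted; tests invert numerically by FFT with the slowly decaying terms
transformed analytically).

Stability is decided by the pole spectrum: all Im(z) > 0 means damped
fluctuations; a pole crossing Im(z) = 0 under a parameter change (e.g.
J ∝ 1/√K upscaling of a delayed inhibitory network) marks a Hopf
bifurcation. Operations requiring stability refuse to run outside the
stable regime; eigenvalue pairs with λ_j + λ_k ≈ 2 (resonance of the
Lyapunov denominators, tolerance 1e−9) and defective W raise explicit
degenerate-case errors rather than being regularized.

## Scaling transformations

`scale_jk` reduces in-degrees by κ (K′ = round(κK)) and sets J′ = J·K/K′,
compensating the rounding exactly so W is preserved entrywise; the drive is
replaced by balanced Poisson + DC reproducing the original working point.
Feasibility requires the new external variance
σ²_ext′ = σ² − σ²_int′ ≥ 0, i.e. κ ≥ κ_min; infeasible requests are
returned flagged, never clipped. The excitatory+inhibitory Poisson variant
(weights J_ext, −g J_ext) is provided for upscaling, where it is the only
regime with nonnegative rates. For binary networks the generic (κ, ι) drive
rule σ²_ext′ = ι²κ[(κ−1)σ²_int + κσ²_ext] preserves mean activities and W.

`binary_zero_lag_scaling` preserves only the zero-lag covariances of the
symmetric binary network by trading the in-degree factor f against a new
relative inhibitory weight g′, with an added Gaussian drive restoring the
working point. The two unknowns are solved by Newton on the 2×2 zero-lag
system (the closed-form expression for g′ agrees to machine precision and
is asserted in tests). The transformation fails at g′ = 1/γ, where the
balanced state bifurcates into silent/saturated solutions.

An equivalent two-step variant exists but is documented only, not
implemented as an operation: (1) change g → g′ at constant connection
probability and re-solve the threshold for the original mean activity;
(2) redistribute synapses so a fraction f̃ comes from inside the network
and 1 − f̃ from a fictitious external pool with the *same* (negative) mean
activity as the internal neurons. Because W_e already changes in step 1,
f̃ differs from the one-step factor f; the one-step Gaussian-drive form is
the tested path.

`symmetric_spiking_scaling` exploits the zero eigenvalue of the rank-one
symmetric two-population connectivity: covariances constrain only the
nonzero-eigenvalue mode, leaving a family of networks
W′ = w′K′·[[1, −b], [c, −bc]] with different sizes (N₁, N₂). At fixed shape
parameter c the four covariance-matching conditions are *linear* in
(1/N₁, 1/N₂) and are solved exactly by least squares; c = 1 solves the full
system (residual ~1e−15), which a trust-region polish over (N₁, N₂, c)
confirms from arbitrary starts. Effective weights enter at quadratic order
in J (the σ²-sensitivity term), as the linear order is insufficient for the
stronger synapses of this construction. Feasibility ends where g′ → 0: the
required sizes diverge and then turn negative. Note that the transformation
itself can be feasible while the *working point* is not realizable by any
nonnegative-variance drive (the required external variance is reported as a
separate diagnostic): for strongly recurrent parameter sets the internal
variance alone can exceed the nominal total.

## Reconstruction

Given cross-spectral matrices C̄(ω) on a frequency grid and a known
interaction model (per-population τ, delay matrix d), the inverse spectrum
is a quadratic polynomial in the unknowns (A, W); a Levenberg–Marquardt fit
(initialized from the high-frequency diagonal, with a few perturbed
restarts) recovers them exactly for noiseless generic instances.
Non-uniqueness is detected two ways: rank deficiency of the fit Jacobian
(the null direction is returned), and structural checks — zero or repeated
eigenvalues, vanishing W entries, and the delay/time-constant symmetry
d_aa − d_ab = d_ga − d_gb at equal τ, under which A and W can be jointly
rescaled without changing the spectrum. Numerically singular frequencies
are dropped with a warning.

## Simulators and estimation

The binary simulator is event-driven with a cached recurrent input per
neuron, updated on state flips; drawing a single global exponential clock
and a uniform neuron choice is equivalent to per-neuron Poisson updates.
Random streams are separated by purpose (connectivity / initial state /
dynamics), so two networks whose inputs differ by a common positive factor
(the J ∝ 1/K vs J ∝ 1/√K drive-matched pair) produce bit-identical state
trajectories from the same seed — asserted as a regression test. The LIF
simulator is clock-driven (default dt = 0.1 ms) with exact subthreshold
propagators for the (V, I) linear system, grid-constrained spikes, ring
buffer delays, and per-step Poisson external input. Grid timing biases
rates downward by O(dt) per inter-spike interval; rates stay within 5% of
the Siegert solve in the fluctuation-driven regime (asserted on a grid of
working points).

Covariances are estimated by averaging over all neuron pairs across two
disjoint groups per population — implemented as the covariance of the two
group-mean signals, which equals the pair average and makes the symmetry
c_ab(Δ) = c_ba(−Δ) exact by construction. Autocovariances average 100
single neurons per population; standard errors come from consecutive time
blocks.

## Known limitations

* The one-pole response kernel with τ_eff = τ_m is a poor approximation of
  the true LIF linear response in the regimes tested: fitted effective time
  constants are 3–8 ms against τ_m = 20 ms, so predicted covariance *time
  courses* decay too slowly even though the integrated (zero-frequency)
  covariances — which depend only on W and the noise diagonal — are
  reproduced. τ_eff is therefore exposed as a per-population override, and
  `fit_tau_eff` calibrates it from a measured covariance course.
* The white spike-train approximation A = r/N overestimates the noise
  input when spiking is sub-Poissonian: at 18–24 spikes/s with a 2 ms
  refractory period the measured ISI CV² is ≈ 0.5–0.6, and integrated
  covariances scale accordingly. The simulation tests validate the
  propagator using the *measured* autocovariance integral as the noise
  amplitude and document the residual ~10–30% discrepancy; the refractory
  dip around zero lag is missed by construction.
* Binary mean-field activities carry a percent-level bias from the
  neglected correlation contribution to the input variance (optional
  switch above) and from the Gaussian approximation of skewed synaptic
  input sums at moderate in-degrees.
* The theory is linear-response around a stationary state: bistable or
  marginally stable networks, mean-driven (resonant) LIF regimes, and
  distributed thresholds/weights/degrees are out of scope.

## Problem sizes and determinism

Simulation-backed tests run shortened versions of the reference runs
(6–20 s of biological time at up to 10,000 neurons); `scripts/acceptance.py`
uses 30 s for the binary network and 15 s at half size (κ = 𝒩 = 0.5,
J ∝ 1/K drive-adjusted — rates are invariant under this reduction, which is
itself one of the claims under test) for the LIF rate measurements. All
simulations are bit-reproducible given (spec, duration, dt, seed); every
seed is derived from the single `--seed` argument.
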