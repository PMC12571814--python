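# Methods

## Oscillator model

The population follows the mean-field Kuramoto dynamics with additive
external drive.  All rate parameters — natural frequencies ω_i, coupling K
and inputs I_i — are specified in Hz and multiplied by 2π inside the
integrator.  This convention preserves the dimensionless ratios K/σ_ω and
I/σ_ω that alone determine the synchronization behaviour (any common
rescaling of ω, K and I cancels in the phase-difference dynamics), while
placing the collective rhythm near 10 Hz so the synthesized EEG sits in the
alpha band.  `angular_units=True` disables the scaling for sensitivity
studies; it changes time scales, not synchrony levels.

Integration is explicit Euler at dt = 0.01 s, with phases reduced mod 2π
after every step (the order parameter is invariant to the reduction).  The
coupling sum is evaluated in mean-field form, Σ_j sin(θ_j − θ_i) =
N·R·sin(ψ − θ_i), which is exact and O(N) per step.  Initial phases are
uniform on [0, 2π) from the run's seed.  An n = 2 run with equal
frequencies reproduces the closed-form two-oscillator solution
d(Δθ)/dt = −2πK sin Δθ to < 0.01 rad at dt = 0.001 s, which bounds the
integrator error at the step sizes used.

**Population size.** N = 10 by default (configurable).  The incoherent
finite-size baseline E[R] ≈ (√π/2)/√N puts the resting level near 0.3 at
N = 10, matching the resting synchrony the three-condition comparison is
built around.  Larger N lowers the resting floor as 1/√N and leaves the
focused level essentially unchanged.

**Condition levels.** With the intrinsic N(10, 2) Hz law the three presets
produce stationary mean R ≈ 0.98 (focused), ≈ 0.41 (multitasking) and
≈ 0.35 (resting) over 20 seeds.  Multitasking forms two internally locked
clusters separated by the 10 Hz input split; their relative phase rotates,
so R(t) oscillates rapidly and only its time average is meaningful.  Note
that at K/σ_ω = 5 the focused condition sits close to full lock: a
stationary level of ≈ 0.8 is not a fixed point of these dynamics at that
coupling (the critical coupling is ≈ 3.2 in the same units), so partially
synchronized focused states require either weaker coupling or broader
frequency spread (the uniform 5–20 Hz law yields ≈ 0.82).

**Firing-rate laws.** `intrinsic` fixes N(10, 2) Hz; `gaussian` is N(mu,
sigma) with mu ∈ [5, 20] Hz and sigma ∈ [1, 5] Hz (defaults 12.5/3, the
midpoints); `poisson_model` is uniform on [5, 20] Hz — the name denotes the
high-variability firing regime it emulates, not the distribution.  Under
strong coupling the clustered Gaussian law locks more tightly and more
smoothly than the uniform law (within-run std of stationary R ≈ 0.010 vs
≈ 0.034), and at rest it retains slightly more coherence (mean R ≈ 0.32 vs
≈ 0.31).  Across-seed or within-run *resting* variance does not separate
the two laws: at K = 1 both are deeply subcritical and share the same
finite-size fluctuation level.

## Signal synthesis

The raw EEG-like trace is the mean-field signal (1/N) Σ cos θ_j.  P_EEG is
its analytic-signal envelope squared, smoothed with a 0.25 s moving
average and affinely rescaled to [0.4, 0.8]; the BOLD-like S_fMRI is the
synchrony (or EEG-power) series convolved with a canonical double-gamma
HRF and rescaled to [0.3, 0.7].  These normalized ranges are plausible
feature ranges, and the affine rescale means only the *shape* of the
features carries information.  A constant input degenerates the rescale;
the midpoint is returned with a flag.

The HRF is the difference of two gamma densities (shapes 6 and 16, scale
1 s, undershoot ratio 1:6), peak-normalized to 1, peak at 5.0 s, kernel
length 32 s.  Convolution is causal and truncated to the input length.
The task regressor is a 20 s on/off boxcar starting "on".

Simulated regions are linear mixtures of the HRF-convolved task and
EEG-power regressors plus white noise: Prefrontal (0.6, 0.3), Parietal
(0.3, 0.6), Motor (0.1, 0.1), Visual (0.1, 0.1, assumed equal to Motor),
ACC (0.45, 0.45); default noise_sd = 0.02 on unit-scale regressors.
Voxels are their region's series plus independent noise (10 per region, 50
total).  **A structural caveat:** because every region shares the same two
regressors, near-perfect GLM fits and weak motor connectivity are mutually
exclusive.  Motor's (0.1, 0.1) weight direction bisects the prefrontal and
parietal weight vectors, so whenever noise is small enough for R² ≥ 0.99
the prefrontal–motor correlation exceeds prefrontal–parietal.  The
"weakly connected motor cortex" pattern emerges only when the weakly
driven regions are noise-dominated (noise_sd ≈ 0.3), and the connectivity
checks are run at that level; the GLM-fidelity checks use the default.

A 0.2 s onset delay (right shift, zero-filled) emulates biological
response latency; it is applied in comparison experiments only, never
during control.

## Energy and reward

E(t) = αR + β|dR/dt| + γP_EEG + δS_fMRI with (α, β, γ, δ) =
(10.01, 5.00, 3.00, 2.00).  The absolute derivative is the default so that
energy is a non-negative cost (a literal signed mode exists for fidelity
experiments); values are normalized model outputs, not Joules.  The reward
r = −(|R_target − R| + E) is therefore bounded above by zero.

Inside the control loop the energy is evaluated at the decision-interval
timescale: interval means of R and finite differences of successive
interval means.  At full dynamics resolution the multitasking regime's
10 Hz oscillation of R(t) pushes β|dR/dt| to ≈ 70, two orders above the
tracking term, and every policy collapses to oscillation suppression; the
interval-level evaluation keeps the transition cost meaningful at the
timescale on which the agent acts.  Open-loop analysis (`energy_trace`)
retains the literal full-resolution form.

Because E with these weights still spans ≈ [2, 14] while the tracking
error is ≤ 1, the environment reward applies an `energy_scale` (default
0.05 ≈ 1/(α+β+γ+δ)) to E, implementing equal baseline weighting of the two
penalties.  The `energy()`/`reward()` primitives are unscaled.

## Control problem

One episode is 200 decision steps of 0.1 s (20 s simulated).  Episodes
cycle deterministically through focused → multitasking → resting, which
keeps 20-episode learning-curve windows comparable for the plateau
criterion.  The synchrony target is condition-dependent — focused 0.9,
multitasking 0.5, resting 0.1 — reflecting a desired synchrony level per
cognitive state.  Actions adjust the coupling constant by {−1, 0, +1},
clipped to [0, 15].  Coupling is the lever used because a uniformly applied
external input provably cannot move the order parameter (it cancels in all
phase differences; the package keeps a `uniform_input` mode that
demonstrates this, and a `split_input` mode for targeted stimulation of
half the population).

The tabular agent sees only (R, E) bins (10 × 10; E clipped to [0, 20]),
while the DQN state is (R, E/20, condition one-hot).  The task context is
thus hidden from the tabular agent by construction, and since the optimal
action at a given R depends on the condition's target, its state is
genuinely aliased.  This is the mechanism behind the DQN's advantage in
the comparison experiment (≈ 45–60% relative reduction in mean
|R_target − R| across training seeds); on a single-condition environment
the tabular agent learns cleanly and its reward curve rises.

Hyperparameters (all configurable): η = 0.1, discount 0.95, ε decaying
exponentially 1.0 → 0.05 with time constant episodes/6; DQN hidden sizes
64/64, replay 10⁴, batch 64, target refresh every 100 gradient steps, Adam
step 10⁻³, warm-up 200 transitions.  The tabular budget is 100 episodes
and the DQN budget 300, with greedy evaluation on 20 fresh episodes.  The
DQN is a numpy MLP with hand-written backpropagation and Adam, which keeps
training deterministic under one seeded generator.  "Stabilization" of a
learning curve is the first episode from which every 20-episode moving
mean stays within 5% of the final-quartile mean.

## Measurement stack

Band power: Welch periodogram, 2 s Hann segments, 50% overlap at
fs = 100 Hz, integrated over the band (alpha 8–12 Hz, beta 13–30 Hz).
Instantaneous phase: 4th-order zero-phase Butterworth band-pass, then the
analytic-signal angle; filter transients are excluded by the callers'
trimming.  PLV is |⟨e^{iΔφ}⟩|; circular mean/std follow the standard
resultant-vector definitions (std = √(−2 ln R̄); zero resultant flags an
undefined direction).  Lag is the argmax of the normalized
cross-correlation (positive = second series trails).  GLM is OLS via
statsmodels with per-coefficient t and two-sided p; no multiple-testing
correction is applied anywhere, matching uncorrected pairwise reporting.
ICA is scikit-learn FastICA on standardized channels, components ordered
by explained variance with sign fixed at the largest-magnitude peak.

## What the synthetic data do and do not show

The generators emulate band-limited oscillatory EEG-like signals at 100 Hz
and slow HRF-shaped BOLD-like signals with known ground truth, which is
what makes exact recovery checks (GLM coefficients in 95% CIs, ICA source
recovery, known lags) possible.  They contain no measurement noise floors,
no artifacts, no volume conduction, no physiological confounds and no
structural connectivity, so green tests here certify the *methods* and the
*closed loop*, not fidelity to any real recording.  Multimodal CSV
fixtures (300 samples × 3 conditions) are balanced by construction;
real-data trial structure is not modeled.

## Numerical choices and degenerate inputs

Euler only (acceptance-level results are defined on it); phases reduced
mod 2π; affine rescales degenerate to midpoints with a flag on constant
input; empty phase vectors, constant signals entering phase/lag
estimators, rank-deficient GLM designs (offending columns named), and
out-of-range model parameters raise ValueError.  ε-greedy ties break
toward the lowest action index.  Seeds propagate through
numpy Generators; every public simulation entry point is reproducible
bit-for-bit for a fixed seed.

## Problem sizes

Default problem sizes are chosen at desk scale: N = 10 oscillators, 10 s
condition runs (20 seeds), 100/300-episode RL budgets (5 seeds), 1,000
BOLD timepoints, 50 voxels.  These are the sizes at which all reported
numbers in the README and the acceptance report are computed.
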