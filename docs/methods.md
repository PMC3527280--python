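# Methods

This note documents the models implemented in `betaclc`, the design
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real recordings.

## Band isolation

Beta amplitude and phase come from convolution with a complex Gabor atom
`g(t) = 2^(1/4) e^{−s0/4} exp(−π t² e^{−s0}) exp(i 2π v0 t)`. The kernel is
written with an explicit imaginary unit in the carrier so the output is an
analytic (complex) signal from which amplitude and phase follow directly.
The duration parameter maps to bandwidth as σ_f(power) = √(e^{−s0}/(4π)):
the amplitude spectrum of the kernel is Gaussian with std √(e^{−s0}/(2π)),
and the *power* spectrum is narrower by √2. At the default `s0 = −5.075`
and `v0 = 28 Hz` this gives σ_f = 3.57 Hz; for frequency banks the per-
frequency `s0` keeps the relative bandwidth constant (σ_f = v0/7.84).
Convolution is FFT-based and zero-phase (the kernel is centered); the
kernel is truncated at ±5 temporal standard deviations, which keeps the
residual amplitude ripple on a pure tone below 10⁻⁶ relative. Edge samples
within half a kernel length are flagged in a validity mask that every
downstream estimator honors; they are never imputed. Phase is 0 at the
oscillation peak of the band-passed real signal and ±π at the trough.
Amplitude normalization divides by the grand mean over valid samples,
after concatenation, per task — so normalized amplitudes are relative
modulations with mean exactly 1.

A useful identity: a unit cosine at the center frequency produces analytic
amplitude 2^(−3/4)·e^{s0/4} (`spectral.tone_response`). Dividing by this
factor converts analytic amplitude to the physical envelope of the
band-passed signal; the array generator relies on it to remove and
re-insert the oscillation.

## Equal-count binning and the parametric fits

The rate mappings use the sort → truncate → partition procedure: of N
samples (masked samples removed first), the trailing N − N_t are dropped
so N_t is the largest multiple of the bin count, rows are stably sorted by
the conditioning value (ties broken by original index, so results are
deterministic), and consecutive blocks of P = N_t/n_b samples form the
bins. Per-bin rate is (S_R/P)·(spike count). Because bins have identical
counts, the count-weighted mean of bin rates equals the truncated-data
global rate exactly — asserted in the tests for every estimator call.
Defaults: 25 bins univariate; 8 amplitude × 16 phase bins for the joint
mapping (chosen so a 300-s recording still leaves thousands of samples
per cell).

Fits: the cosine model is solved in closed form (it is linear in
(offset, α, β) with depth √(α²+β²) ≥ 0). The sigmoid, von Mises-type and
joint 7-parameter models use trust-region least squares with a grid of
8 (sigmoid), 4 (von Mises) or 3 (joint, warm-started from the univariate
fits) starts, bound p4 ≥ 10⁻³ (so the slope sign is carried by p2), and
concentration bounded in [10⁻³, 50]. The best finite-cost solution is
kept; if no start formally converges a warning is emitted, and a `FitError`
is raised only when every start fails outright. The joint fit is
canonicalized so the phase weight at mean amplitude (p5 + p6) is
non-negative, with the preferred phase absorbing the sign.

Identifiability: `R_PHASE` is defined as the unit cosine `cos(θ − p7)`,
making `w_AMP(a) = p5·a + p6·a²` exact (b1 = p5, b2 = p6) — the additive/
multiplicative decomposition otherwise leaves the scale split ambiguous.
Two caveats documented by the recovery tests: the tanh offset/half-range
pair trades off when the observed amplitude support does not reach both
plateaus (the fitted *curve* is still accurate), and the von Mises offset
trades off against the flat trough of the exponential; recovery is
therefore asserted against per-parameter scales (baseline rate for rate
offsets, curve range for the von Mises offset, support span for amplitude
locations, radians for angles).

The permutation test uses the across-bin variance of binned rates as its
statistic (the choice of statistic was open) and builds the null by
circular rotation of the spike vector with a minimum offset of 1 s, which
preserves the spike train's autocorrelation while destroying its alignment
to the conditioning series; p = (1 + #{null ≥ observed})/(1 + n_perm),
1000 permutations by default. Type-I calibration at α ∈ {0.01, 0.05} is
verified by simulation over 200 null units.

Split-half designs partition by trial parity (trials numbered from 1 in
table order; samples between center-cue onset and reward offset belong to
their trial, samples outside trials are excluded). Trial-stage windows:
Move-to-Center = center-on → center-enter, Move-to-Target = go →
target-enter, Reward = reward-on → reward-off (stage names are standard,
their boundaries were an open choice). Amplitude quartiles are equal-count
splits.

## Inter-hemispheric and inter-channel phase relations

Phase differences are wrapped to [−π, π); their distribution is summarized
by a histogram plus a von Mises fit (circular-mean direction, concentration
from inverting A(κ) = I₁(κ)/I₀(κ) at the mean resultant length, capped at
κ = 50 for near-degenerate series). The distance law is estimated by
filtering all 64 channels, computing the pairwise mean resultant of
exp(i(θ_i − θ_j)) (one Gram-matrix product), inverting to κ̂ per pair,
pooling pairs within distance classes (unique grid distances rounded to
10⁻⁶ mm), and fitting an unweighted least-squares line of class-mean κ̂ on
distance. Lagged amplitude conditioning uses equal-count phase-difference
bins; positive lag means the amplitude series is taken later than the
phase-difference series.

## Ensemble analyses

Crossovers of two amplitude-to-rate sigmoids (baselines included) are
found by sign changes on a 10⁴-point grid refined by Brent's method,
deduplicated within 10⁻⁴ amplitude units. Rank-order states merge all
pairwise crossovers into interval boundaries and rank units by descending
fitted rate at interval midpoints (ties broken by unit index); identical
adjacent states are collapsed. The analysis domain defaults to the bulk of
the observed normalized amplitude (tails are data-starved). The analytic
sequence can resolve states narrower than a grid step, so the grid-oracle
test checks mutual consistency at the grid's resolution rather than exact
equality. Preferred phases convert to lags via
wrap(p3 − θ_trough)/(2π)·(1000/v0) ms with θ_trough = −π, so a trough-
preferring unit has lag 0 and one 28-Hz cycle spans ≈ 36 ms. First-spiker
fractions segment cycles at phase wraps (trough to trough), keep cycles
where each of the two units fires exactly once and no sample is masked,
and exclude (but count) cycles where both spikes share a 1-ms bin.

## Multivariate model

The spike-triggered and baseline distributions over multichannel beta
coefficients are augmented complex Gaussians: mean and covariance of
x_B = [x; conj(x)], which captures both the Hermitian covariance and the
pseudo-covariance of an improper signal. The covariance receives diagonal
shrinkage λ·(trace/2N)·I with λ = 10⁻⁴ (spike-triggered sample counts can
be small; the data likelihood is otherwise untouched, and λ = 0 recovers
the empirical covariance exactly). Log-densities are evaluated through the
exact isomorphism to the 2N-dimensional real Gaussian on [Re x; Im x]
(covariance M R_B M^H, M = ½[[I, I], [−iI, iI]]), using a Cholesky
factorization of the real covariance; the complex-form evaluation is kept
and agrees to 10⁻¹³ in the tests. Channel inputs are amplitude-normalized
per channel before fitting (an open choice, documented here).

Rate prediction follows a three-block protocol: the densities are fitted
on the first half of the training data, the L-to-rate sigmoid is
calibrated by equal-count binning on the *second* half (a fresh block),
and evaluation uses held-out test data. Calibrating on the same samples
that shaped the spike-triggered density inflates the apparent L-rate
relation and produces evaluation slopes well below 1 on test data; with
fresh-block calibration the held-out measured-vs-predicted slope is ≈ 1
for self-consistent units. Channel-subset analyses use nested concentric
square groups (4/16/36/64) around the spike electrode (Chebyshev-distance
ranking); cross-task transfer runs the four train/test task combinations
with trial-parity train/test splits.

## The synthetic-data generator

The generator's defaults are the study conditions; they are fixed, not
tuned per experiment.

* **Trials.** Self-initiated center-out trials with task-specific holds
  (center 500 ms MC / 100 ms BC; target 400 ms MC / 50 ms BC), 500-ms
  reward, movement durations from a configurable law (default uniform
  0.4–3 s, capped at 10 s; the real distribution is unknown), targets in
  shuffled blocks of 8 so counts differ by at most one.
* **Meso signals.** Each hemisphere is 1/f² background (spectrally shaped
  Gaussian noise, flat below 1 Hz) plus an amplitude-modulated 28-Hz
  oscillation. The envelope is log-normal — AR(1) on log-amplitude with a
  200-ms time constant and σ_log = 0.4, mean-corrected to 1 — multiplied
  by an event-locked gain (drop to 0.35 during movement, rise to 1.25
  during reward, 100-ms smoothed transitions; only the qualitative shape
  of event-related desynchronization is prescribed by the phenomenon).
  The oscillation scale is calibrated numerically (one Welch measurement
  per component) so the spectral peak sits at −46 dB in 10·log10(µV²/Hz),
  with the background 30 dB below the peak at 28 Hz. The background level
  is deliberately low: the Gabor filter integrates ≈ 9 Hz of noise
  bandwidth, and a stronger in-band background would contaminate the
  phase-difference and phase-coupling statistics the generator is required
  to control. Real recordings have a stronger 1/f; the trade-off is
  documented rather than hidden. Because the low-frequency 1/f rise can
  exceed the beta peak in absolute density, the spectral-peak locator
  searches 10–100 Hz — the standard way to identify an oscillatory peak
  riding on a 1/f background.
* **Inter-hemispheric phase difference.** A slow wrapped-normal AR(1)
  process (300-ms time constant) whose stationary resultant matches the
  configured von Mises concentration (default κ = 2, centered at zero).
* **Array LFPs.** Every channel shares the meso oscillation up to a
  channel-specific phase jitter. The jitter is a Gaussian field over
  channels, slowly varying in time (AR(1), 400-ms time constant), whose
  spatial covariance is calibrated through the concentration-composition
  curve: pairwise wrapped-difference variance v(d) satisfies
  exp(−v/2) = A(κ_target(d)) for the linear law κ(d) = 2.67 − 0.4435·d
  (any law with κ > 0 at the maximal distance is accepted). Two
  corrections matter: the injected variance is inflated by the inverse of
  the filter's temporal-smoothing attenuation of the AR(1) jitter
  (computed from the AR(1) spectrum and the kernel's squared frequency
  response — without it the recovered intercept is biased up by ≈ 0.12),
  and the field's common mode is projected out (pairwise differences are
  unchanged; the spatial average stays phase-locked to the meso signal).
  The covariance is eigenvalue-clipped to the nearest PSD matrix; the
  perturbation to the implied pairwise variances is negligible on the
  8×8 grid. Per-channel white noise (std 0.3 × mean envelope) adds a
  phase-noise floor that shifts κ̂ by well under 0.01.
* **Spikes.** Per-1-ms Bernoulli draws with rate r_baseline + r_trial +
  r_target + p2·tanh((a−p3)/(2p4)) + (b1·a + b2·a²)·cos(θ − φ_pref)
  [+ optional von Mises phase-difference term], clipped at 0; rates above
  1000 spikes/s (bin saturation) are an error. The amplitude and phase a
  unit is driven by are those of the analytic signal the caller passes,
  so estimator validation is free of attenuation bias by construction.
  The default ensemble draws baselines 8–30 spikes/s, makes ~60% of units
  amplitude-negative, flips the amplitude-slope sign in the other task for
  30% of units, and shifts every unit's BC preferred phase 0.8 rad earlier
  than MC — the remapping structure is present by construction, with
  magnitudes chosen as plausible rather than measured values.

**What passing tests show — and don't.** Parameter recovery, calibrated
type-I error, and within-task > cross-task ordering on these synthetic
data establish that the estimators are correct and well-calibrated under
the generative model they assume (additive rate composition, Poisson-like
spiking, stationary coupling within task). They do not establish effect
sizes, population percentages, or coupling structure in real recordings,
where spike-history dependence, non-stationarity, unit isolation quality
and stronger 1/f backgrounds all intrude.

## Problem sizes

Recovery suites use 300-s recordings (with 75/150/300-s nested subsets for
the RMSE-vs-duration check) and 6–12 replicates; the permutation
calibration uses 200 null units × 500 permutations on 60-s records; the
multivariate analyses use 200–300-s records with 16 channels for transfer
(64 for the channel-subset sweep). The staged pipeline defaults to 120 s,
60 trials and 6 units per task. These sizes give comfortable
signal-to-noise for every asserted property while keeping a full run of
the test suite in the minutes range.

## Known limitations

* The generator couples all units to the meso-scale signal; channel-
  specific spatial preferences beyond the shared oscillation (and hence
  strong gains from distal channels in the multivariate model) are not
  emulated.
* The phase-difference-to-rate term uses the spatially averaged signals;
  the per-electrode variant is available as an option but has no reference
  behavior to validate against.
* Movement kinematics, spike waveforms and biophysical network structure
  are out of scope; r_trial/r_target are piecewise-stage effects, not
  kinematic regressions.
* The von Mises-type rate fit has a sign ambiguity (p2 < 0 represents a
  trough at p4); comparisons across fits should use the curve argmax
  (`preferred_phase_diff`), which the package canonicalizes.
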