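# betaclc

Cross-level coupling (CLC) analysis between single-neuron spiking and the
sensorimotor beta rhythm, with a synthetic-data generator standing in for
bilateral macaque motor-cortex recordings.

In motor cortex the spike rate of a neuron depends not only on external
factors (movement target, trial stage) but also on the ongoing ~28-Hz beta
oscillation of the local field potential (LFP): on its instantaneous
amplitude, its phase, the phase *difference* between hemispheres, and the
multichannel spatial pattern across a microelectrode array — and these
dependencies can remap when the subject switches task (manual reaching, MC,
vs brain-machine-interface cursor control, BC). This package implements the
full estimation pipeline for such coupling and a generator that produces
recordings with known ground-truth coupling, so every estimator can be
validated by parameter recovery.

## The models

The beta signal is extracted by convolution with a complex Gabor atom

    g(t) = 2^(1/4) e^(−s0/4) exp(−π t² e^(−s0)) exp(i 2π v0 t),

with center frequency `v0 = 28 Hz` and duration parameter `s0 = −5.075`
(power-spectrum Gaussian std 3.57 Hz); `a_t = |z_t|` is the beta amplitude
(normalized so its grand mean is 1) and `θ_t = arg z_t` the beta phase.
Spike-rate mappings are estimated by equal-count binning (sort samples by
the conditioning value, partition into bins with identical counts) and fit
with

* amplitude-to-rate  `F_S(a) = p1 + p2 tanh((a − p3)/(2 p4))`
* phase-to-rate      `F_C(θ) = p1 + p2 cos(θ − p3)`
* phase-difference-to-rate  `F_D(φ) = p1 + p2 exp(p3 cos(φ − p4))`
* joint beta-to-rate `F_B(a, θ) = p1 + p2 tanh((a − p3)/(2 p4)) + (p5 a + p6 a²) cos(θ − p7)`

with the decomposition `R_BETA = R_AMP(a) + w_AMP(a)·R_PHASE(θ)`,
`w_AMP(a) = p5 a + p6 a²`. Significance comes from a circular-rotation
permutation test. Spatial-pattern coupling uses augmented complex Gaussian
distributions over multichannel beta coefficients (baseline vs
spike-triggered), a per-sample log-likelihood ratio `L(x) =
log[p_ST(x)/p_BASE(x)]`, and a sigmoid L-to-rate calibration giving a
predicted instantaneous rate `R_EST = F_S(L)`. Ensemble consequences —
amplitude-indexed spike-rate rank-order states from sigmoid crossovers,
preferred-phase-to-lag spike-timing tables, within-cycle first-spiker
fractions — are computed from the fitted mappings.

The generator reproduces the statistical structure the estimators assume:
a 28-Hz spectral peak at −46 dB (10·log10(µV²/Hz)) over a 1/f² background,
event-locked beta desynchronization, near-zero-lag inter-hemispheric phase
coupling, an 8×8 array (0.5 mm pitch) whose pairwise phase-coupling
concentration follows κ(d) = 2.67 − 0.4435·d, and Bernoulli spike trains
from the additive beta-to-rate model with distinct parameter sets per task.

## Worked example

```python
import numpy as np
from betaclc import synth, spectral, mappings, ensemble

# 300 s of synthetic meso-scale LFP, no task events
meso = synth.generate_meso_lfp(trials=None, duration_s=300.0, desync=None, seed=42)
beta = spectral.normalize_amplitude(spectral.filter_signal(meso.s_L, 28.0))

# a unit that fires less at high beta amplitude, preferring phase 1.0 rad
truth = synth.TaskParams(r_baseline=20.0, amp_p2=-6.0, amp_p3=1.0, amp_p4=0.2,
                         phase_pref=1.0, w_b1=4.0, w_b2=1.0)
spikes = synth.generate_spikes(truth, None, beta, seed=43)

amp_map = mappings.equal_count_binning(beta.amplitude, spikes, 25, valid=beta.valid)
sig = mappings.fit_sigmoid(amp_map)
ph_map = mappings.equal_count_binning(beta.phase, spikes, 25, valid=beta.valid)
cos = mappings.fit_cosine(ph_map)
p = mappings.permutation_test(beta.amplitude, spikes, n_perm=1000, seed=44,
                              valid=beta.valid)
```

Printing the fitted quantities (plus
`ensemble.preferred_phase_to_lag(cos, 28.0)`) gives:

```
mean rate            20.21 spikes/s
sigmoid fit  p1=19.61 p2=-5.22 p3=1.02 p4=0.16
cosine fit   baseline=20.21 depth=5.03 pref=0.90 rad
permutation p-value  0.0010
preferred lag after trough  23.0 ms
```

The fitted sigmoid recovers the configured negative amplitude coupling
(true half-range −6 spikes/s, estimated −5.2; the amplitude support does
not fully saturate the tanh, so the raw half-range is estimated with some
shrinkage while the fitted curve itself tracks the truth closely). The
cosine fit recovers the baseline (20), the effective modulation depth
(w_AMP at the mean amplitude ≈ b1·E[a] + b2·E[a²] ≈ 5.1 spikes/s) and the
preferred phase (true 1.0 rad). The permutation p-value sits at the floor
1/(n_perm+1), flagging significant amplitude coupling, and the preferred
phase converts to a most-probable spike time 23 ms after the beta trough
(one 28-Hz cycle spans ≈ 36 ms).

A full staged run (simulate → filter → fit → states → predict → report)
is available from the command line:

```bash
betaclc run --seed 3 --out runs/demo          # all stages
betaclc fit --config my.yaml --out runs/demo  # one stage, YAML config
```

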