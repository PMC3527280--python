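"""Synthetic trials, multichannel LFPs and ground-truth spike trains.

Everything downstream of this module is estimation; this module is the
generator whose parameters the estimators must recover.  It emulates the
statistical structure of bilateral motor-cortex recordings during a
delayed center-out task performed under Manual Control (MC, arm reaching)
or Brain Control (BC, BMI cursor control):

* trial/event tables with task-specific hold times (center hold 500 ms MC
  / 100 ms BC, target hold 400 ms MC / 50 ms BC, 500 ms reward);
* meso-scale LFPs with a 28-Hz beta peak at -46 dB (10*log10(uV^2/Hz))
  over a 1/f^2 background, go-cue-locked beta desynchronization, and an
  inter-hemispheric beta phase difference concentrated near zero;
* 8x8 array LFPs (0.5 mm pitch) whose pairwise 28-Hz phase-coupling
  concentration follows a linear distance law, kappa(d) = a + b*d,
  calibrated numerically through the von Mises concentration-composition
  curve;
* spike trains drawn per 1-ms bin from the additive beta-to-rate model

      rate(t) = r_baseline + r_trial(t) + r_target(t)
                + R_AMP(a_t) + w_AMP(a_t) * cos(theta_t - phi_pref)
                [+ phase-difference term],  clipped at 0,

  with distinct parameter sets per task so that task-dependent remapping
  is present by construction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import spectral
from .macro import besselratio, wrap_angle

__all__ = [
    "CENTER_HOLD_MS",
    "TARGET_HOLD_MS",
    "REWARD_MS",
    "MAX_MOVEMENT_MS",
    "TRIAL_COLUMNS",
    "DesyncProfile",
    "MesoLFP",
    "LFPArray",
    "SpikeTrain",
    "TaskParams",
    "UnitGroundTruth",
    "generate_trials",
    "validate_trials",
    "generate_meso_lfp",
    "generate_array_lfp",
    "generate_spikes",
    "rate_function",
    "default_ensemble",
    "export_ground_truth",
    "load_ground_truth",
    "save_lfp_h5",
    "load_lfp_h5",
    "spikes_to_csv",
    "spikes_from_csv",
]

CENTER_HOLD_MS = {"MC": 500.0, "BC": 100.0}
TARGET_HOLD_MS = {"MC": 400.0, "BC": 50.0}
REWARD_MS = 500.0
MAX_MOVEMENT_MS = 10_000.0

TRIAL_COLUMNS = [
    "trial_id", "task", "target_id",
    "t_center_on", "t_center_enter", "t_go",
    "t_target_enter", "t_reward_on", "t_reward_off",
    "movement_duration",
]


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

def _draw_durations(law, n: int, rng: np.random.Generator) -> np.ndarray:
    """Movement durations in ms from a distribution spec.

    ``("fixed", v)``, ``("uniform", lo, hi)``, or a callable ``f(n, rng)``.
    """
    if callable(law):
        d = np.asarray(law(n, rng), dtype=float)
    elif law[0] == "fixed":
        d = np.full(n, float(law[1]))
    elif law[0] == "uniform":
        d = rng.uniform(float(law[1]), float(law[2]), size=n)
    else:
        raise ValueError(f"unknown movement-duration law: {law!r}")
    if np.any(d <= 0) or np.any(d > MAX_MOVEMENT_MS):
        raise ValueError("movement durations must lie in (0, 10000] ms")
    return d


def generate_trials(
    task: str,
    n_trials: int,
    movement_duration_law=("uniform", 400.0, 3000.0),
    seed: int = 0,
    approach_ms=(300.0, 700.0),
    intertrial_ms=(200.0, 500.0),
    t_start_ms: float = 1000.0,
) -> pd.DataFrame:
    """Generate a trial/event table for one task.

    Targets cycle pseudo-randomly over 1-8 in shuffled blocks, so counts
    per target differ by at most 1.  Timestamps are in ms and strictly
    increasing within and across trials.
    """
    if task not in CENTER_HOLD_MS:
        raise ValueError(f"invalid task label {task!r}; expected 'MC' or 'BC'")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    durations = _draw_durations(movement_duration_law, n_trials, rng)

    n_blocks = int(np.ceil(n_trials / 8))
    targets = np.concatenate([rng.permutation(8) + 1 for _ in range(n_blocks)])[:n_trials]

    rows = []
    t = float(t_start_ms)
    for i in range(n_trials):
        t_center_on = t
        t_center_enter = t_center_on + rng.uniform(*approach_ms)
        t_go = t_center_enter + CENTER_HOLD_MS[task]
        t_target_enter = t_go + durations[i]
        t_reward_on = t_target_enter + TARGET_HOLD_MS[task]
        t_reward_off = t_reward_on + REWARD_MS
        rows.append((
            i, task, int(targets[i]),
            t_center_on, t_center_enter, t_go,
            t_target_enter, t_reward_on, t_reward_off,
            durations[i],
        ))
        t = t_reward_off + rng.uniform(*intertrial_ms)
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def validate_trials(trials: pd.DataFrame) -> None:
    """Raise if the trial table violates its invariants."""
    ts_cols = ["t_center_on", "t_center_enter", "t_go",
               "t_target_enter", "t_reward_on", "t_reward_off"]
    ts = trials[ts_cols].to_numpy(float)
    if not np.all(np.diff(ts, axis=1) > 0):
        raise ValueError("timestamps not strictly increasing within a trial")
    for task, g in trials.groupby("task"):
        if not np.allclose(g["t_go"] - g["t_center_enter"], CENTER_HOLD_MS[task]):
            raise ValueError(f"center hold does not match task {task}")
        if not np.allclose(g["t_reward_on"] - g["t_target_enter"], TARGET_HOLD_MS[task]):
            raise ValueError(f"target hold does not match task {task}")
    if not np.allclose(trials["t_reward_off"] - trials["t_reward_on"], REWARD_MS):
        raise ValueError("reward period must last 500 ms")
    md = trials["movement_duration"].to_numpy(float)
    if not np.allclose(md, trials["t_target_enter"] - trials["t_go"]):
        raise ValueError("movement_duration inconsistent with event times")
    if np.any(md > MAX_MOVEMENT_MS):
        raise ValueError("movement duration exceeds 10 s")
    if not trials["target_id"].between(1, 8).all():
        raise ValueError("target_id outside 1-8")


# ---------------------------------------------------------------------------
# meso-scale LFP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesyncProfile:
    """Event-locked multiplicative gain on the beta envelope.

    The envelope drops to ``move_gain`` during the movement (go cue to
    target entry) and rises to ``reward_gain`` during reward delivery;
    transitions are smoothed with a Gaussian of ``ramp_ms``.
    """

    move_gain: float = 0.35
    reward_gain: float = 1.25
    ramp_ms: float = 100.0


@dataclass
class MesoLFP:
    """Spatially averaged per-hemisphere signals plus generator ground truth."""

    s_L: np.ndarray
    s_R: np.ndarray
    fs: float
    f0: float
    envelope_L: np.ndarray  # oscillation envelope in uV (incl. event gain)
    envelope_R: np.ndarray
    phase_diff: np.ndarray  # ground-truth inter-hemispheric phase difference
    gain: np.ndarray        # event-locked gain profile (1 if no desync)


def _ar1_fast(n: int, tau_s: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) (discrete Ornstein-Uhlenbeck), vectorized via lfilter."""
    from scipy.signal import lfilter
    rho = float(np.exp(-1.0 / (tau_s * fs)))
    eps = rng.standard_normal(n) * np.sqrt(1.0 - rho**2)
    eps[0] = rng.standard_normal()  # stationary start
    return lfilter([1.0], [1.0, -rho], eps)


def _one_over_f_background(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power-spectral slope -2 (amplitude ~ 1/f), flat below 1 Hz."""
    w = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = 1.0 / np.maximum(f, 1.0)
    shape[0] = 0.0
    return np.fft.irfft(w * shape, n)


def _event_gain(n: int, fs: float, trials: pd.DataFrame | None,
                desync: DesyncProfile | None) -> np.ndarray:
    gain = np.ones(n)
    if trials is None or desync is None or len(trials) == 0:
        return gain
    idx = lambda ms: int(np.clip(round(ms * fs / 1000.0), 0, n - 1))
    for _, tr in trials.iterrows():
        gain[idx(tr.t_go):idx(tr.t_target_enter)] = desync.move_gain
        gain[idx(tr.t_reward_on):idx(tr.t_reward_off)] = desync.reward_gain
    # soften transitions
    sig = desync.ramp_ms * fs / 1000.0 / 2.0
    half = int(np.ceil(4 * sig))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sig) ** 2)
    k /= k.sum()
    return np.convolve(gain, k, mode="same")


def _measured_peak_density(x: np.ndarray, fs: float, f0: float) -> float:
    """Linear-scale Welch PSD maximum within f0 +- 3 Hz."""
    from scipy.signal import welch
    f, p = welch(x, fs=fs, nperseg=min(4096, len(x)), window="hann")
    m = (f >= f0 - 3.0) & (f <= f0 + 3.0)
    return float(p[m].max())


def generate_meso_lfp(
    trials: pd.DataFrame | None,
    duration_s: float,
    psd_peak_freq: float = 28.0,
    psd_peak_level_db: float = -46.0,
    desync: DesyncProfile | None = DesyncProfile(),
    hemi_kappa: float = 2.0,
    env_tau_s: float = 0.2,
    env_log_std: float = 0.4,
    env_share: float = 0.5,
    background_rel_db: float = -30.0,
    fs: float = 1000.0,
    seed: int = 0,
) -> MesoLFP:
    """Generate the two meso-scale (spatial-average-like) signals s_L, s_R.

    Each signal is 1/f^2 background plus an amplitude-modulated oscillation
    at ``psd_peak_freq``; the oscillation amplitude is calibrated
    numerically (one Welch measurement per component) so the spectral peak
    sits at ``psd_peak_level_db`` in 10*log10(uV^2/Hz), with the background
    ``background_rel_db`` below it at the peak frequency.  The slow
    envelope is log-normal (AR(1) on log-amplitude, time constant
    ``env_tau_s``), multiplied by the event-locked desynchronization gain.
    The inter-hemispheric phase difference is a slow process whose
    stationary wrapped distribution has von Mises concentration
    ``hemi_kappa`` centered at zero.
    """
    n = int(round(duration_s * fs))
    if trials is not None and len(trials) > 0:
        if trials["t_reward_off"].max() / 1000.0 > duration_s:
            raise ValueError("duration shorter than trial span")
    rng = np.random.default_rng(seed)

    # slow log-normal envelope, partially shared across hemispheres
    l_c = _ar1_fast(n, env_tau_s, fs, rng)
    l_l = np.sqrt(env_share) * l_c + np.sqrt(1 - env_share) * _ar1_fast(n, env_tau_s, fs, rng)
    l_r = np.sqrt(env_share) * l_c + np.sqrt(1 - env_share) * _ar1_fast(n, env_tau_s, fs, rng)
    env_l = np.exp(env_log_std * l_l - env_log_std**2 / 2.0)
    env_r = np.exp(env_log_std * l_r - env_log_std**2 / 2.0)

    gain = _event_gain(n, fs, trials, desync)

    # inter-hemispheric phase difference: wrapped-normal AR(1) whose
    # stationary resultant matches A(hemi_kappa)
    v_hemi = -2.0 * np.log(besselratio(hemi_kappa))
    phi = np.sqrt(v_hemi) * _ar1_fast(n, 0.3, fs, rng)

    t = np.arange(n) / fs
    psi = 2.0 * np.pi * psd_peak_freq * t + 0.3 * _ar1_fast(n, 1.0, fs, rng)
    osc_l = env_l * gain * np.cos(psi + phi / 2.0)
    osc_r = env_r * gain * np.cos(psi - phi / 2.0)

    bg_l = _one_over_f_background(n, fs, rng)
    bg_r = _one_over_f_background(n, fs, rng)

    # calibration: background level at f0, then oscillation scale so that
    # total peak density hits the target
    peak_lin = 10.0 ** (psd_peak_level_db / 10.0)
    bg_target = 10.0 ** ((psd_peak_level_db + background_rel_db) / 10.0)
    bg_scale = np.sqrt(bg_target / _measured_peak_density(bg_l, fs, psd_peak_freq))
    bg_l *= bg_scale
    bg_r *= bg_scale
    osc_peak = _measured_peak_density(osc_l, fs, psd_peak_freq)
    c = np.sqrt(max(peak_lin - bg_target, 0.0) / osc_peak)

    return MesoLFP(
        s_L=bg_l + c * osc_l,
        s_R=bg_r + c * osc_r,
        fs=fs,
        f0=psd_peak_freq,
        envelope_L=c * env_l * gain,
        envelope_R=c * env_r * gain,
        phase_diff=wrap_angle(phi),
        gain=gain,
    )


# ---------------------------------------------------------------------------
# array LFP with distance-dependent phase coupling
# ---------------------------------------------------------------------------

@dataclass
class LFPArray:
    """8x8 microelectrode-array LFP block (uV, 1 kHz)."""

    data: np.ndarray       # (channels x samples), float32 uV
    fs: float
    pitch_mm: float
    hemisphere: str
    coords_mm: np.ndarray  # (channels x 2)

    def validate(self) -> None:
        if self.data.shape[0] != self.coords_mm.shape[0]:
            raise ValueError("channel count mismatch between data and coords")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite LFP values")


def grid_coords(shape=(8, 8), pitch_mm: float = 0.5) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return np.column_stack([ii.ravel() * pitch_mm, jj.ravel() * pitch_mm]).astype(float)


def generate_array_lfp(
    meso: np.ndarray,
    seed: int = 0,
    grid_shape=(8, 8),
    pitch_mm: float = 0.5,
    kappa_law=(2.67, -0.4435),
    jitter: bool = True,
    jitter_tau_s: float = 0.4,
    channel_noise_std_rel: float = 0.3,
    hemisphere: str = "L",
    v0: float = 28.0,
    fs: float = 1000.0,
) -> LFPArray:
    """Expand a meso signal into a 64-channel array with a kappa(d) law.

    Mechanism: the meso oscillation (its band-passed component at ``v0``)
    is shared by all channels up to a channel-specific phase jitter.  The
    jitter is a slowly varying Gaussian field over channels whose spatial
    covariance is calibrated so that the wrapped pairwise phase-difference
    variance v(d) satisfies exp(-v(d)/2) = A(kappa_target(d)) — i.e. a von
    Mises concentration estimate on any channel pair recovers the target
    linear law kappa(d) = intercept + slope*d.  The covariance is
    eigenvalue-clipped to the nearest positive semidefinite matrix.

    With ``jitter=False`` all channels are identical copies of the meso
    signal (pairwise concentration then sits at the estimation cap).
    """
    meso = np.asarray(meso, dtype=float)
    coords = grid_coords(grid_shape, pitch_mm)
    n_ch = coords.shape[0]
    n = meso.size
    rng = np.random.default_rng(seed)

    if not jitter:
        data = np.repeat(meso[None, :], n_ch, axis=0).astype(np.float32)
        return LFPArray(data, fs, pitch_mm, hemisphere, coords)

    intercept, slope = kappa_law
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    kap_t = intercept + slope * d
    if np.any(kap_t[d > 0] <= 0):
        raise ValueError("kappa law non-positive at the largest inter-electrode distance")

    # wrapped-normal variance per distance: exp(-v/2) = A(kappa)
    v = -2.0 * np.log(besselratio(np.where(d > 0, kap_t, 1.0)))
    v[d == 0] = 0.0
    # the band filter's Gaussian temporal smoothing attenuates the slow
    # AR(1) jitter variance; inflate the injected variance to compensate
    # (attenuation computed from the AR(1) spectrum and the kernel's
    # squared frequency response)
    s0 = spectral.s0_for_bandwidth(v0 / spectral.RELATIVE_BANDWIDTH)
    sigma_t = np.sqrt(np.exp(s0) / (2.0 * np.pi))
    f = np.linspace(0.0, 20.0 / jitter_tau_s, 4001)
    spec_ar1 = 1.0 / (1.0 + (2.0 * np.pi * f * jitter_tau_s) ** 2)
    att = float(np.trapezoid(spec_ar1 * np.exp(-4.0 * np.pi**2 * f**2 * sigma_t**2), f)
                / np.trapezoid(spec_ar1, f))
    v = v / att
    v_max = v.max()
    sigma = np.where(d > 0, (v_max - v) / 2.0, v_max / 2.0)
    np.fill_diagonal(sigma, v_max / 2.0)
    evals, evecs = np.linalg.eigh(sigma)
    chol = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    g = np.vstack([_ar1_fast(n, jitter_tau_s, fs, rng) for _ in range(n_ch)])
    delta = chol @ g
    # remove the common mode: pairwise differences (which set kappa) are
    # untouched, while the spatial average stays phase-locked to the meso
    delta -= delta.mean(axis=0, keepdims=True)

    # physical envelope: analytic amplitude rescaled by the filter's tone
    # response, so meso - env*cos(theta) removes the in-band oscillation
    s0 = spectral.s0_for_bandwidth(v0 / spectral.RELATIVE_BANDWIDTH)
    sig = spectral.filter_signal(meso, v0, s0=s0, fs=fs)
    gain = spectral.tone_response(s0)
    amp = np.abs(sig.z) / gain
    th = np.angle(sig.z)
    resid = meso - amp * np.cos(th)
    mean_amp = float(amp[sig.valid].mean())

    data = resid[None, :] + amp[None, :] * np.cos(th[None, :] + delta)
    data += rng.normal(scale=channel_noise_std_rel * mean_amp, size=data.shape)
    return LFPArray(data.astype(np.float32), fs, pitch_mm, hemisphere, coords)


# ---------------------------------------------------------------------------
# ground truth and spikes
# ---------------------------------------------------------------------------

@dataclass
class TaskParams:
    """Ground-truth beta-to-rate parameters for one unit in one task.

    The amplitude term is ``amp_p2 * tanh((a - amp_p3) / (2 amp_p4))``
    (offset folded into ``r_baseline``); the phase term is
    ``(w_b1 a + w_b2 a^2) cos(theta - phase_pref)``; the optional
    phase-difference term is ``pd_p2 * exp(pd_p3 cos(phi - pd_p4))``.
    """

    r_baseline: float = 20.0
    amp_p2: float = 0.0
    amp_p3: float = 1.0
    amp_p4: float = 0.25
    phase_pref: float = 0.0
    w_b1: float = 0.0
    w_b2: float = 0.0
    pd_p2: float = 0.0
    pd_p3: float = 1.0
    pd_p4: float = 0.0
    target_pref: int = 1
    target_depth: float = 0.0
    r_trial: dict = field(default_factory=lambda: {
        "move_to_center": 0.0, "move_to_target": 0.0, "reward": 0.0,
    })

    def __post_init__(self):
        self.phase_pref = float(wrap_angle(self.phase_pref))
        self.pd_p4 = float(wrap_angle(self.pd_p4))


@dataclass
class UnitGroundTruth:
    """Per-task parameter sets for one simulated unit."""

    unit_id: str
    tasks: dict  # {"MC": TaskParams, "BC": TaskParams}


@dataclass
class SpikeTrain:
    """Binary 1-kHz spike vector for one unit."""

    unit_id: str
    x: np.ndarray  # uint8, 1 = spike in that 1-ms bin
    fs: float = 1000.0

    @property
    def n_spikes(self) -> int:
        return int(self.x.sum())

    @property
    def rate(self) -> float:
        return self.n_spikes / (self.x.size / self.fs)

    def validate(self) -> None:
        if not np.isin(np.unique(self.x), [0, 1]).all():
            raise ValueError("spike vector entries must be 0 or 1")


def _stage_masks(n: int, fs: float, trials: pd.DataFrame):
    """Boolean sample masks for the three trial stages."""
    masks = {s: np.zeros(n, dtype=bool) for s in
             ("move_to_center", "move_to_target", "reward")}
    windows = {
        "move_to_center": ("t_center_on", "t_center_enter"),
        "move_to_target": ("t_go", "t_target_enter"),
        "reward": ("t_reward_on", "t_reward_off"),
    }
    for stage, (c0, c1) in windows.items():
        for a, b in zip(trials[c0].to_numpy(), trials[c1].to_numpy()):
            i0 = int(np.clip(round(a * fs / 1000.0), 0, n))
            i1 = int(np.clip(round(b * fs / 1000.0), 0, n))
            masks[stage][i0:i1] = True
    return masks


def rate_function(
    p: TaskParams,
    amplitude: np.ndarray,
    phase: np.ndarray,
    phase_diff: np.ndarray | None = None,
    trials: pd.DataFrame | None = None,
    fs: float = 1000.0,
) -> np.ndarray:
    """Ground-truth instantaneous rate (spikes/s), clipped at 0."""
    a = np.asarray(amplitude, float)
    th = np.asarray(phase, float)
    rate = np.full(a.shape, p.r_baseline, dtype=float)
    rate += p.amp_p2 * np.tanh((a - p.amp_p3) / (2.0 * p.amp_p4))
    rate += (p.w_b1 * a + p.w_b2 * a**2) * np.cos(th - p.phase_pref)
    if phase_diff is not None and p.pd_p2 != 0.0:
        rate += p.pd_p2 * np.exp(p.pd_p3 * np.cos(np.asarray(phase_diff) - p.pd_p4))
    if trials is not None and len(trials) > 0:
        masks = _stage_masks(a.size, fs, trials)
        for stage, m in masks.items():
            rate[m] += p.r_trial.get(stage, 0.0)
        if p.target_depth != 0.0:
            for _, tr in trials.iterrows():
                i0 = int(round(tr.t_go * fs / 1000.0))
                i1 = int(round(tr.t_target_enter * fs / 1000.0))
                tune = p.target_depth * np.cos(
                    2.0 * np.pi * (tr.target_id - p.target_pref) / 8.0
                )
                rate[i0:i1] += tune
    return np.clip(rate, 0.0, None)


def generate_spikes(
    gt,
    task: str | None,
    analytic: spectral.AnalyticSignal,
    phase_diff: np.ndarray | None = None,
    trials: pd.DataFrame | None = None,
    seed: int = 0,
) -> SpikeTrain:
    """Bernoulli spikes per 1-ms bin from the ground-truth rate model.

    ``gt`` is a :class:`UnitGroundTruth` (with ``task`` selecting the
    parameter set) or a bare :class:`TaskParams`.  The analytic signal must
    be amplitude-normalized (mean amplitude 1); invalid edge samples use
    mean amplitude and no phase modulation.
    """
    if isinstance(gt, UnitGroundTruth):
        p = gt.tasks[task]
        unit_id = gt.unit_id
    else:
        p, unit_id = gt, "unit"
    if not analytic.normalized:
        raise ValueError("analytic signal must be amplitude-normalized first")
    a = np.where(analytic.valid, np.abs(analytic.z), 1.0)
    th = np.angle(analytic.z)
    rate = rate_function(p, a, th, phase_diff, trials, analytic.fs)
    rate[~analytic.valid] = np.clip(p.r_baseline, 0.0, None)
    if rate.max() > analytic.fs:
        raise ValueError(
            f"rate {rate.max():.1f} spikes/s exceeds bin saturation ({analytic.fs}/s)"
        )
    rng = np.random.default_rng(seed)
    x = (rng.random(rate.size) < rate / analytic.fs).astype(np.uint8)
    return SpikeTrain(unit_id=unit_id, x=x, fs=analytic.fs)


def default_ensemble(
    n_units: int = 12,
    seed: int = 0,
    bc_phase_shift: float = -0.8,
    flip_fraction: float = 0.3,
    pd_fraction: float = 0.4,
) -> list[UnitGroundTruth]:
    """A diverse ensemble with task-dependent remapping built in.

    BC amplitude slopes are negative for ~60% of units; a ``flip_fraction``
    of units reverse the slope sign in MC; every unit's BC preferred phase
    is the MC phase shifted by ``bc_phase_shift`` rad (earlier); a
    ``pd_fraction`` of units carry a phase-difference term whose preferred
    difference flips by pi across tasks.
    """
    rng = np.random.default_rng(seed)
    units = []
    for i in range(n_units):
        base = float(rng.uniform(8.0, 30.0))
        amp_sign = -1.0 if rng.random() < 0.6 else 1.0
        amp_depth = float(rng.uniform(0.10, 0.35)) * base
        p3 = float(rng.normal(1.0, 0.05))
        p4 = float(rng.uniform(0.15, 0.35))
        pref_mc = float(rng.uniform(-np.pi, np.pi))
        depth = float(rng.uniform(0.15, 0.40)) * base
        u = float(rng.uniform(-0.3, 0.8))   # quadratic share: sub- to supra-linear
        b2, b1 = depth * u, depth * (1.0 - u)
        tgt = int(rng.integers(1, 9))
        tgt_depth = float(rng.uniform(0.0, 0.3)) * base
        r_trial = {s: float(rng.uniform(-0.1, 0.1)) * base
                   for s in ("move_to_center", "move_to_target", "reward")}
        has_pd = rng.random() < pd_fraction
        pd_p2 = float(rng.uniform(0.05, 0.15)) * base if has_pd else 0.0
        pd_p3 = float(rng.uniform(0.5, 2.0))
        pd_p4 = float(rng.uniform(-np.pi, np.pi))

        bc = TaskParams(
            r_baseline=base, amp_p2=amp_sign * amp_depth, amp_p3=p3, amp_p4=p4,
            phase_pref=wrap_angle(pref_mc + bc_phase_shift),
            w_b1=b1, w_b2=b2,
            pd_p2=pd_p2, pd_p3=pd_p3, pd_p4=pd_p4,
            target_pref=tgt, target_depth=tgt_depth, r_trial=dict(r_trial),
        )
        flip = rng.random() < flip_fraction
        mc_scale = float(rng.uniform(0.6, 1.6))
        mc = TaskParams(
            r_baseline=base * float(rng.uniform(0.8, 1.2)),
            amp_p2=amp_sign * amp_depth * mc_scale * (-1.0 if flip else 1.0),
            amp_p3=p3, amp_p4=p4,
            phase_pref=pref_mc,
            w_b1=b1 * mc_scale, w_b2=b2 * mc_scale,
            pd_p2=pd_p2, pd_p3=pd_p3,
            pd_p4=wrap_angle(pd_p4 + np.pi) if has_pd else pd_p4,
            target_pref=tgt, target_depth=tgt_depth, r_trial=dict(r_trial),
        )
        units.append(UnitGroundTruth(unit_id=f"unit{i:03d}", tasks={"BC": bc, "MC": mc}))
    return units


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def export_ground_truth(units: list[UnitGroundTruth], path: str) -> None:
    """Write the full ground-truth record (both task parameter sets) as JSON."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"directory does not exist: {parent}")
    payload = [
        {"unit_id": u.unit_id,
         "tasks": {k: asdict(v) for k, v in u.tasks.items()}}
        for u in units
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_ground_truth(path: str) -> list[UnitGroundTruth]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        UnitGroundTruth(
            unit_id=rec["unit_id"],
            tasks={k: TaskParams(**v) for k, v in rec["tasks"].items()},
        )
        for rec in payload
    ]


def save_lfp_h5(path: str, array: LFPArray) -> None:
    import h5py
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("lfp", data=array.data.astype(np.float32))
        ds.attrs["fs"] = array.fs
        ds.attrs["grid_pitch_mm"] = array.pitch_mm
        ds.attrs["hemisphere"] = array.hemisphere
        fh.create_dataset("coords_mm", data=array.coords_mm)


def load_lfp_h5(path: str) -> LFPArray:
    import h5py
    with h5py.File(path, "r") as fh:
        ds = fh["lfp"]
        return LFPArray(
            data=ds[...],
            fs=float(ds.attrs["fs"]),
            pitch_mm=float(ds.attrs["grid_pitch_mm"]),
            hemisphere=str(ds.attrs["hemisphere"]),
            coords_mm=fh["coords_mm"][...],
        )


def spikes_to_csv(trains: list[SpikeTrain], path: str) -> None:
    rows = []
    for tr in trains:
        times = np.nonzero(tr.x)[0] * 1000.0 / tr.fs
        rows.extend((tr.unit_id, t) for t in times)
    pd.DataFrame(rows, columns=["unit_id", "time_ms"]).to_csv(path, index=False)


def spikes_from_csv(path: str, n_samples: int, fs: float = 1000.0) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    trains = []
    for uid, g in df.groupby("unit_id", sort=True):
        x = np.zeros(n_samples, dtype=np.uint8)
        idx = np.round(g["time_ms"].to_numpy() * fs / 1000.0).astype(int)
        x[idx] = 1
        trains.append(SpikeTrain(unit_id=str(uid), x=x, fs=fs))
    return trains
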