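"""Gabor analytic-signal filtering and event-related averaging.

Band isolation uses a complex Gabor atom — a Gaussian-enveloped complex
exponential — parameterized by a center frequency ``v0`` (Hz) and a
log-scale duration parameter ``s0``.  Convolving a real signal with the
complex atom yields a complex series whose modulus is the instantaneous
band amplitude and whose argument is the instantaneous band phase.

Phase convention: the kernel carries ``exp(+i 2 pi v0 t)``, so the phase of
the filtered series is 0 at an oscillation peak of the band-passed real
signal and +-pi at a trough.

The duration parameter relates to bandwidth as follows.  The temporal
Gaussian is ``exp(-pi t^2 e^{-s0})``, whose amplitude spectrum is Gaussian
with standard deviation ``sqrt(e^{-s0} / (2 pi))`` Hz; the *power* spectrum
is narrower by sqrt(2), giving

    sigma_f(power) = sqrt(e^{-s0} / (4 pi)).

With ``s0 = -5.075`` this evaluates to 3.57 Hz at any center frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "GaborParams",
    "AnalyticSignal",
    "gabor_atom",
    "gabor_power_sigma_hz",
    "s0_for_bandwidth",
    "filter_signal",
    "normalize_amplitude",
    "spatial_average",
    "semilog_frequencies",
    "event_locked_average",
    "psth",
    "tf_map",
    "rt_sorted_map",
    "welch_psd_db",
    "psd_beta_peak",
]

DEFAULT_S0 = -5.075
#: ratio v0 / sigma_f(power) implied by s0 = -5.075 at v0 = 28 Hz; used to
#: keep relative bandwidth constant across a frequency bank.
RELATIVE_BANDWIDTH = 28.0 / np.sqrt(np.exp(5.075) / (4.0 * np.pi))


@dataclass(frozen=True)
class GaborParams:
    """Center time (s), center frequency (Hz) and duration parameter."""

    t0: float
    v0: float
    s0: float

    def __post_init__(self):
        if self.v0 <= 0:
            raise ValueError("center frequency v0 must be positive")


@dataclass
class AnalyticSignal:
    """Complex band-filtered series with an edge-validity mask.

    Attributes
    ----------
    z : complex ndarray
        Filtered series; ``abs(z)`` is amplitude, ``angle(z)`` is phase.
    fs : float
        Sampling rate in Hz.
    v0 : float
        Center frequency of the filter in Hz.
    valid : bool ndarray
        False for edge samples within half a kernel length of the ends.
    normalized : bool
        True once the amplitude has been scaled to unit mean.
    """

    z: np.ndarray
    fs: float
    v0: float
    valid: np.ndarray
    normalized: bool = False

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.z)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.z)

    def __len__(self) -> int:
        return self.z.size


def gabor_power_sigma_hz(s0: float) -> float:
    """Standard deviation (Hz) of the Gaussian power-spectrum profile."""
    return float(np.sqrt(np.exp(-s0) / (4.0 * np.pi)))


def s0_for_bandwidth(sigma_f_hz: float) -> float:
    """Duration parameter giving a power-spectrum Gaussian std of ``sigma_f_hz``."""
    return float(-np.log(4.0 * np.pi * sigma_f_hz**2))


def tone_response(s0: float) -> float:
    """Amplitude of the filtered output for a unit-amplitude cosine at v0.

    A real tone cos(2 pi v0 t) maps to z(t) = (1/2) Ghat(v0) exp(i 2 pi
    v0 t) where Ghat(v0) = 2^(1/4) e^{s0/4} is the kernel's Fourier
    transform at its center frequency, so the closed-form response is
    2^(-3/4) e^{s0/4}.  Dividing the analytic amplitude by this factor
    converts it to the physical envelope of the band-passed signal.
    """
    return float(2.0 ** -0.75 * np.exp(s0 / 4.0))


def _temporal_sigma_s(s0: float) -> float:
    # exp(-pi t^2 e^{-s0}) == exp(-t^2 / (2 sigma_t^2))
    return float(np.sqrt(np.exp(s0) / (2.0 * np.pi)))


def gabor_atom(params: GaborParams, support: np.ndarray) -> np.ndarray:
    """Evaluate the complex Gabor atom on a sample grid (seconds).

    g(t) = 2^(1/4) exp(-s0/4) exp(-pi (t-t0)^2 e^{-s0}) exp(i 2 pi v0 (t-t0))

    The support must span at least +-4 temporal standard deviations around
    ``t0`` so the truncated kernel carries essentially all of its energy.
    """
    t = np.asarray(support, dtype=float)
    sigma_t = _temporal_sigma_s(params.s0)
    if t.min() > params.t0 - 4.0 * sigma_t or t.max() < params.t0 + 4.0 * sigma_t:
        raise ValueError(
            "support too short: need at least +-4 temporal std "
            f"({4 * sigma_t:.4f} s) around t0"
        )
    dt = t - params.t0
    envelope = 2.0 ** 0.25 * np.exp(-params.s0 / 4.0) * np.exp(
        -np.pi * dt**2 * np.exp(-params.s0)
    )
    return envelope * np.exp(2j * np.pi * params.v0 * dt)


def _kernel(v0: float, s0: float, fs: float, n_sigmas: float = 5.0) -> np.ndarray:
    sigma_t = _temporal_sigma_s(s0)
    half = int(np.ceil(n_sigmas * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    return gabor_atom(GaborParams(0.0, v0, s0), t)


def filter_signal(
    x: np.ndarray,
    v0: float,
    s0: float | None = None,
    fs: float = 1000.0,
) -> AnalyticSignal:
    """Convolve a real signal with the complex Gabor atom at ``v0`` Hz.

    If ``s0`` is omitted it is chosen for a constant relative bandwidth
    (power-spectrum std of ``v0 / 7.84`` Hz, i.e. 3.57 Hz at 28 Hz).
    Edge samples within half a kernel length are masked invalid.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input signal contains non-finite values")
    if v0 >= fs / 2:
        raise ValueError(f"v0={v0} Hz is at or above Nyquist ({fs / 2} Hz)")
    if s0 is None:
        s0 = s0_for_bandwidth(v0 / RELATIVE_BANDWIDTH)
    g = _kernel(v0, s0, fs)
    half = (len(g) - 1) // 2
    if x.size < len(g):
        raise ValueError("signal shorter than the filter kernel")
    # zero-phase: kernel is centered, fftconvolve 'same' keeps alignment
    z = sps.fftconvolve(x, g, mode="same") / fs
    valid = np.ones(x.size, dtype=bool)
    valid[:half] = False
    valid[x.size - half:] = False
    return AnalyticSignal(z=z, fs=fs, v0=v0, valid=valid)


def normalize_amplitude(analytic: AnalyticSignal) -> AnalyticSignal:
    """Scale so the mean amplitude over valid samples is exactly 1.

    Phases are untouched (a positive real scaling of ``z``).
    """
    if not np.any(analytic.valid):
        raise ValueError("no valid samples to normalize over")
    mean_amp = float(np.mean(np.abs(analytic.z[analytic.valid])))
    if mean_amp == 0.0:
        raise ValueError("all-zero amplitude; cannot normalize")
    return replace(analytic, z=analytic.z / mean_amp, normalized=True)


def spatial_average(array) -> np.ndarray:
    """Per-sample arithmetic mean across channels (meso-scale signal).

    Accepts a (channels x samples) ndarray or an object with a ``.data``
    attribute of that shape.  Warns (but proceeds) if the channel count is
    not the expected 64 of one microelectrode array.
    """
    data = np.asarray(getattr(array, "data", array), dtype=float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D (channels x samples) array")
    if data.shape[0] != 64:
        warnings.warn(
            f"expected 64 channels, got {data.shape[0]}; averaging anyway",
            stacklevel=2,
        )
    return data.mean(axis=0)


def semilog_frequencies(fmin: float = 1.0, fmax: float = 300.0, n: int = 40) -> np.ndarray:
    """Logarithmically spaced center-frequency bank."""
    return np.geomspace(fmin, fmax, n)


def _epochs(series: np.ndarray, events_ms: np.ndarray, window_ms, fs: float):
    series = np.asarray(series, dtype=float)
    events = np.asarray(events_ms, dtype=float)
    if events.size == 0:
        raise ValueError("zero usable events")
    lo = int(round(window_ms[0] * fs / 1000.0))
    hi = int(round(window_ms[1] * fs / 1000.0))
    idx = np.round(events * fs / 1000.0).astype(int)
    if np.any(idx + lo < 0) or np.any(idx + hi >= series.size):
        raise ValueError("event window extends outside the recording")
    offsets = np.arange(lo, hi + 1)
    return series[idx[:, None] + offsets[None, :]], offsets * 1000.0 / fs


def event_locked_average(
    series: np.ndarray,
    events_ms: np.ndarray,
    window_ms=(-1000.0, 10000.0),
    fs: float = 1000.0,
):
    """Mean of event-locked epochs of a series.

    Returns ``(t_ms, mean_trace)`` where ``t_ms`` is time relative to the
    event.  Every window must lie inside the recording.
    """
    ep, t = _epochs(series, events_ms, window_ms, fs)
    return t, ep.mean(axis=0)


def psth(
    spike_vector: np.ndarray,
    events_ms: np.ndarray,
    window_ms=(-1000.0, 10000.0),
    fs: float = 1000.0,
    smooth_ms: float | None = None,
):
    """Event-locked mean spike rate (spikes/s), optionally Gaussian-smoothed."""
    t, m = event_locked_average(spike_vector, events_ms, window_ms, fs)
    rate = m * fs
    if smooth_ms is not None and smooth_ms > 0:
        sig = smooth_ms * fs / 1000.0
        half = int(np.ceil(4 * sig))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sig) ** 2)
        k /= k.sum()
        # normalize by the local kernel mass so edges are unbiased
        rate = np.convolve(rate, k, mode="same") / np.convolve(
            np.ones_like(rate), k, mode="same")
    return t, rate


def tf_map(
    x: np.ndarray,
    events_ms: np.ndarray,
    freqs: np.ndarray,
    window_ms=(-1000.0, 10000.0),
    fs: float = 1000.0,
):
    """Event-locked time-frequency amplitude map.

    For each center frequency the signal is filtered, its amplitude is
    normalized to a mean of 1 over valid samples, and event-locked epochs
    are averaged.  Values are therefore relative amplitude modulations.
    Returns ``(freqs, t_ms, map)`` with ``map`` of shape (n_freqs, n_times).
    """
    rows = []
    t = None
    for f in np.asarray(freqs, dtype=float):
        amp = normalize_amplitude(filter_signal(x, f, fs=fs)).amplitude
        t, m = event_locked_average(amp, events_ms, window_ms, fs)
        rows.append(m)
    return np.asarray(freqs, dtype=float), t, np.vstack(rows)


def rt_sorted_map(
    amplitude: np.ndarray,
    trials,
    window_trials: int = 250,
    window_ms=(-1000.0, 3000.0),
    fs: float = 1000.0,
):
    """Movement-duration-sorted sliding-window average of go-cue epochs.

    Trials are sorted by ``movement_duration``; row ``i`` of the result is
    the mean epoch over sorted trials ``i .. i + window_trials - 1``,
    aligned to the go cue.  Returns ``(t_ms, matrix, sorted_durations)``.
    """
    df = trials.sort_values("movement_duration").reset_index(drop=True)
    n = len(df)
    if n < window_trials:
        raise ValueError(f"need at least {window_trials} trials, got {n}")
    ep, t = _epochs(amplitude, df["t_go"].to_numpy(), window_ms, fs)
    c = np.cumsum(ep, axis=0)
    top = c[window_trials - 1:] - np.vstack([np.zeros(ep.shape[1]), c[:-window_trials]])
    rows = top / window_trials
    return t, rows, df["movement_duration"].to_numpy()


def welch_psd_db(x: np.ndarray, fs: float = 1000.0, nperseg: int = 4096):
    """Welch power spectral density in 10*log10(units^2/Hz)."""
    f, p = sps.welch(x, fs=fs, nperseg=min(nperseg, len(x)), window="hann")
    with np.errstate(divide="ignore"):
        return f, 10.0 * np.log10(p)


def psd_beta_peak(
    x: np.ndarray,
    fs: float = 1000.0,
    fmin: float = 10.0,
    fmax: float = 100.0,
    nperseg: int = 4096,
):
    """Locate the oscillatory spectral peak riding on the 1/f background.

    Searches the Welch PSD within ``[fmin, fmax]`` — the band where the
    sensorimotor beta/gamma peak lives, above the low-frequency 1/f rise —
    and returns ``(peak_freq_hz, peak_level_db)``.
    """
    f, pdb = welch_psd_db(x, fs=fs, nperseg=nperseg)
    m = (f >= fmin) & (f <= fmax)
    if not np.any(m):
        raise ValueError("empty search band")
    i = np.argmax(pdb[m])
    return float(f[m][i]), float(pdb[m][i])
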