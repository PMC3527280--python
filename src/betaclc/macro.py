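"""Inter-hemispheric and inter-channel phase relations.

Covers the macro-scale side of cross-level coupling: the wrapped phase
difference between the left and right meso-scale beta signals, its von
Mises description, the distance law of pairwise phase-coupling
concentration across a microelectrode array, and lagged conditioning of
beta amplitudes on the phase difference.

Concentration estimates use the standard von Mises machinery: the mean
resultant length R of a phase sample maps to the maximum-likelihood
concentration through the Bessel-function ratio A(kappa) = I1(kappa) /
I0(kappa); near-degenerate samples are capped at ``KAPPA_CAP`` to avoid
infinities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .spectral import AnalyticSignal, filter_signal

__all__ = [
    "KAPPA_CAP",
    "PhaseDiffSeries",
    "PhaseDiffDensity",
    "DistanceKappaFit",
    "besselratio",
    "kappa_from_resultant",
    "wrap_angle",
    "phase_difference",
    "circular_correlation",
    "fit_phase_diff_distribution",
    "pairwise_kappa",
    "distance_kappa_fit",
    "lagged_amplitude_conditioning",
]

#: ceiling for concentration estimates from near-identical phase samples
KAPPA_CAP = 50.0


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(a) + np.pi, 2.0 * np.pi) - np.pi


def besselratio(kappa) -> np.ndarray:
    """A(kappa) = I1(kappa) / I0(kappa), the mean resultant of a von Mises."""
    kappa = np.asarray(kappa, dtype=float)
    return special.i1e(kappa) / special.i0e(kappa)


def kappa_from_resultant(r: float, cap: float = KAPPA_CAP) -> float:
    """Invert A(kappa) = r for the ML concentration estimate.

    Solved by bracketing (A is strictly increasing); values of ``r`` at or
    above ``A(cap)`` return ``cap``.
    """
    if not np.isfinite(r) or r <= 0.0:
        return 0.0
    if r >= besselratio(cap):
        return float(cap)
    return float(optimize.brentq(lambda k: besselratio(k) - r, 1e-12, cap))


@dataclass
class PhaseDiffSeries:
    """Wrapped per-sample phase difference theta_L - theta_R with validity mask."""

    phi: np.ndarray
    fs: float
    valid: np.ndarray

    def __len__(self) -> int:
        return self.phi.size


@dataclass
class PhaseDiffDensity:
    """Normalized histogram over [-pi, pi) plus a von Mises fit."""

    bin_edges: np.ndarray
    density: np.ndarray  # sums to 1 over bins
    mu: float
    kappa: float


@dataclass
class DistanceKappaFit:
    """Per-distance concentration estimates and the linear law kappa(d)."""

    distances_mm: np.ndarray
    kappa_by_distance: np.ndarray
    n_pairs: np.ndarray
    intercept: float
    slope_per_mm: float
    degenerate: bool = False
    pair_records: list = field(default_factory=list)


def phase_difference(left: AnalyticSignal, right: AnalyticSignal) -> PhaseDiffSeries:
    """Wrapped inter-hemispheric phase difference theta_L - theta_R."""
    if len(left) != len(right):
        raise ValueError("analytic signals differ in length")
    if left.v0 != right.v0:
        raise ValueError("analytic signals have different center frequencies")
    phi = wrap_angle(np.angle(left.z) - np.angle(right.z))
    return PhaseDiffSeries(phi=phi, fs=left.fs, valid=left.valid & right.valid)


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Jammalamadaka-SenGupta circular correlation coefficient."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am = np.angle(np.mean(np.exp(1j * a)))
    bm = np.angle(np.mean(np.exp(1j * b)))
    sa = np.sin(wrap_angle(a - am))
    sb = np.sin(wrap_angle(b - bm))
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        return 0.0
    return float(np.sum(sa * sb) / denom)


def fit_phase_diff_distribution(series: PhaseDiffSeries, n_bins: int = 64) -> PhaseDiffDensity:
    """Histogram + maximum-likelihood von Mises fit of a phase-difference series.

    The mean direction is the circular mean; the concentration comes from
    inverting A(kappa) at the mean resultant length.  A degenerate
    (all-equal) series yields the capped concentration with a warning.
    """
    phi = series.phi[series.valid]
    if phi.size < 1000:
        raise ValueError(f"need >= 1000 valid samples, got {phi.size}")
    z = np.mean(np.exp(1j * phi))
    mu = float(np.angle(z))
    r = float(np.abs(z))
    if r >= besselratio(KAPPA_CAP):
        warnings.warn("near-degenerate phase-difference series; kappa capped", stacklevel=2)
    kappa = kappa_from_resultant(r)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(phi, bins=edges)
    return PhaseDiffDensity(
        bin_edges=edges, density=counts / counts.sum(), mu=mu, kappa=kappa
    )


def pairwise_kappa(phases: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Matrix of pairwise phase-difference concentrations for stacked phases.

    ``phases`` is (channels x samples) of instantaneous phases.  For every
    channel pair the mean resultant of exp(i (theta_i - theta_j)) is
    inverted to a von Mises concentration (diagonal = cap).
    """
    u = np.exp(1j * np.asarray(phases))
    if valid is not None:
        u = u[:, np.asarray(valid, bool)]
    n = u.shape[1]
    gram = (u @ u.conj().T) / n
    r = np.abs(gram)
    kap = np.empty_like(r)
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            kap[i, j] = kappa_from_resultant(r[i, j]) if i != j else KAPPA_CAP
    return kap


def distance_kappa_fit(array, v0: float = 28.0) -> DistanceKappaFit:
    """Recover the linear law kappa(d) from a multichannel array.

    Filters every channel at ``v0``, estimates the von Mises concentration
    of the phase difference for every channel pair, pools pairs within
    distance classes (unique grid distances, rounded to 1e-6 mm), and fits
    a least-squares line of class-mean concentration on distance.
    """
    data = np.asarray(array.data, dtype=float)
    coords = np.asarray(array.coords_mm, dtype=float)
    n_ch = data.shape[0]
    phases = np.empty_like(data)
    valid = None
    for c in range(n_ch):
        sig = filter_signal(data[c], v0, fs=array.fs)
        phases[c] = np.angle(sig.z)
        valid = sig.valid if valid is None else (valid & sig.valid)
    kap = pairwise_kappa(phases, valid)

    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    iu = np.triu_indices(n_ch, k=1)
    pair_d = np.round(d[iu], 6)
    pair_k = kap[iu]
    classes = np.unique(pair_d)
    if classes.size < 2:
        raise ValueError("need >= 2 distinct inter-electrode distances")
    kbar = np.array([pair_k[pair_d == c].mean() for c in classes])
    npairs = np.array([(pair_d == c).sum() for c in classes])

    degenerate = bool(np.all(pair_k >= KAPPA_CAP - 1e-9))
    if degenerate:
        warnings.warn("all pairwise concentrations at cap; fit degenerate", stacklevel=2)
    slope, intercept = np.polyfit(classes, kbar, 1)
    return DistanceKappaFit(
        distances_mm=classes,
        kappa_by_distance=kbar,
        n_pairs=npairs,
        intercept=float(intercept),
        slope_per_mm=float(slope),
        degenerate=degenerate,
        pair_records=[(float(a), float(b)) for a, b in zip(pair_d, pair_k)],
    )


def lagged_amplitude_conditioning(
    phase_diff: PhaseDiffSeries,
    amp_l: np.ndarray,
    amp_r: np.ndarray,
    lags_ms,
    n_bins: int = 16,
    mode: str = "mean",
):
    """Condition beta amplitude (or L-R amplitude correlation) on the phase
    difference at a set of lags.

    Positive lag means the amplitude series is taken *later* than the
    phase-difference series.  For each lag the (mean of the two) amplitude
    — or, with ``mode='corr'``, the product-moment correlation of the two
    amplitudes — is computed within equal-count phase-difference bins; the
    across-bin range is reported per lag together with the lag maximizing
    that range.

    Returns a dict with per-lag bin supports/curves/ranges and ``best_lag_ms``.
    """
    lags = np.asarray(list(lags_ms), dtype=float)
    if lags.size == 0:
        raise ValueError("empty lag list")
    fs = phase_diff.fs
    phi = phase_diff.phi
    amp_l = np.asarray(amp_l, float)
    amp_r = np.asarray(amp_r, float)
    n = phi.size
    out = {"lags_ms": lags, "ranges": [], "curves": [], "supports": [], "mode": mode}
    for lag in lags:
        k = int(round(lag * fs / 1000.0))
        if abs(k) >= n:
            raise ValueError(f"lag {lag} ms exceeds series length")
        if k >= 0:
            phi_s = phi[: n - k]
            v = phase_diff.valid[: n - k]
            al, ar = amp_l[k:], amp_r[k:]
        else:
            phi_s = phi[-k:]
            v = phase_diff.valid[-k:]
            al, ar = amp_l[: n + k], amp_r[: n + k]
        phi_s, al, ar = phi_s[v], al[v], ar[v]
        order = np.argsort(phi_s, kind="stable")
        m = phi_s.size - (phi_s.size % n_bins)
        order = order[:m]
        per = m // n_bins
        phi_b = phi_s[order].reshape(n_bins, per)
        al_b = al[order].reshape(n_bins, per)
        ar_b = ar[order].reshape(n_bins, per)
        support = phi_b.mean(axis=1)
        if mode == "corr":
            curve = np.array(
                [np.corrcoef(al_b[i], ar_b[i])[0, 1] for i in range(n_bins)]
            )
        else:
            curve = 0.5 * (al_b + ar_b).mean(axis=1)
        out["supports"].append(support)
        out["curves"].append(curve)
        out["ranges"].append(float(curve.max() - curve.min()))
    out["ranges"] = np.asarray(out["ranges"])
    out["best_lag_ms"] = float(lags[int(np.argmax(out["ranges"]))])
    return out
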