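"""Cross-level coupling estimators: binned mappings and parametric fits.

The empirical mapping from a conditioning series (beta amplitude, phase,
or inter-hemispheric phase difference) to spike rate is estimated by
*equal-count* binning: the series and the binary spike vector are
truncated to the largest length divisible by the bin count, sorted by the
conditioning value (stable sort, ties broken by original index), and
partitioned into bins holding exactly the same number of samples.  The
per-bin spike rate is ``S_R / P * (spikes in bin)``.  The count-weighted
mean of the bin rates therefore equals the truncated-data global rate
exactly, for every call.

Parametric models fit to the binned mappings:

* amplitude-to-rate:        F_S(a)      = p1 + p2 tanh((a - p3) / (2 p4))
* phase-to-rate:            F_C(theta)  = p1 + p2 cos(theta - p3)
* phase-difference-to-rate: F_D(phi)    = p1 + p2 exp(p3 cos(phi - p4))
* joint beta-to-rate:       F_B(a, th)  = p1 + p2 tanh((a - p3)/(2 p4))
                                          + (p5 a + p6 a^2) cos(th - p7)

For F_B the decomposition R_BETA = R_AMP + w_AMP * R_PHASE is made
identifiable by defining R_PHASE as the unit cosine cos(theta - p7), so
the amplitude-to-weight mapping is exactly w_AMP(a) = p5 a + p6 a^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import spectral
from .macro import wrap_angle

__all__ = [
    "FitError",
    "BinnedMapping",
    "SigmoidFit",
    "CosineFit",
    "VonMisesRateFit",
    "JointBinning",
    "BetaRateFit",
    "equal_count_binning",
    "fit_sigmoid",
    "fit_cosine",
    "fit_vonmises_rate",
    "joint_binning",
    "fit_beta_rate",
    "permutation_test",
    "split_half_fits",
    "remapping_correlation",
    "condition_mask",
    "conditional_mapping",
    "frequency_profile",
    "external_tuning",
    "evaluate_rate_prediction",
]

DEFAULT_N_BINS = 25


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge from every start."""


# ---------------------------------------------------------------------------
# equal-count binning
# ---------------------------------------------------------------------------

@dataclass
class BinnedMapping:
    """Equal-count binned rate mapping.

    ``support`` is the per-bin mean of the conditioning variable (strictly
    nondecreasing); ``rates`` are spikes/s; every bin holds exactly
    ``samples_per_bin`` samples of the ``n_truncated`` retained.
    """

    name: str
    support: np.ndarray
    rates: np.ndarray
    counts: np.ndarray          # spikes per bin
    n_bins: int
    samples_per_bin: int
    n_total: int
    n_truncated: int
    fs: float

    @property
    def global_rate(self) -> float:
        """Truncated-data mean rate; equals the weighted mean of bin rates."""
        return float(self.counts.sum() * self.fs / self.n_truncated)

    @property
    def rate_range(self) -> float:
        return float(self.rates.max() - self.rates.min())


def _prepare(x, spikes, valid):
    x = np.asarray(x, dtype=float)
    s = np.asarray(getattr(spikes, "x", spikes))
    if x.size != s.size:
        raise ValueError("conditioning series and spike vector differ in length")
    if valid is not None:
        v = np.asarray(valid, bool)
        x, s = x[v], s[v]
    return x, s


def equal_count_binning(
    x,
    spikes,
    n_bins: int = DEFAULT_N_BINS,
    fs: float = 1000.0,
    valid=None,
    name: str = "x",
) -> BinnedMapping:
    """Sort -> truncate -> partition -> per-bin mean/rate.

    Masked samples (``valid`` False) are removed first.  The remaining N
    samples are truncated to N_t, the largest multiple of ``n_bins``
    (dropping the trailing samples in time order), then stably sorted by
    ``x`` and split into ``n_bins`` consecutive blocks of P = N_t/n_bins
    samples each.
    """
    x, s = _prepare(x, spikes, valid)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    n = x.size
    n_t = (n // n_bins) * n_bins
    if n_t < n_bins:
        raise ValueError(f"too little data: {n} samples for {n_bins} bins")
    x, s = x[:n_t], s[:n_t]
    order = np.argsort(x, kind="stable")
    per = n_t // n_bins
    xb = x[order].reshape(n_bins, per)
    sb = s[order].reshape(n_bins, per)
    counts = sb.sum(axis=1).astype(float)
    return BinnedMapping(
        name=name,
        support=xb.mean(axis=1),
        rates=counts * fs / per,
        counts=counts,
        n_bins=n_bins,
        samples_per_bin=per,
        n_total=n,
        n_truncated=n_t,
        fs=fs,
    )


# ---------------------------------------------------------------------------
# parametric fits
# ---------------------------------------------------------------------------

def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


@dataclass
class SigmoidFit:
    """F_S(a) = p1 + p2 tanh((a - p3) / (2 p4)), p4 > 0."""

    p1: float
    p2: float
    p3: float
    p4: float
    r2: float = np.nan

    def __call__(self, a):
        return self.p1 + self.p2 * np.tanh((np.asarray(a, float) - self.p3) / (2.0 * self.p4))

    @property
    def params(self):
        return np.array([self.p1, self.p2, self.p3, self.p4])


@dataclass
class CosineFit:
    """F_C(theta) = p1 + p2 cos(theta - p3), depth p2 >= 0."""

    p1: float
    p2: float
    p3: float
    r2: float = np.nan

    def __call__(self, theta):
        return self.p1 + self.p2 * np.cos(np.asarray(theta, float) - self.p3)

    @property
    def preferred_phase(self) -> float:
        return self.p3

    @property
    def modulation_depth(self) -> float:
        return self.p2

    @property
    def params(self):
        return np.array([self.p1, self.p2, self.p3])


@dataclass
class VonMisesRateFit:
    """F_D(phi) = p1 + p2 exp(p3 cos(phi - p4)), concentration p3 > 0."""

    p1: float
    p2: float
    p3: float
    p4: float
    r2: float = np.nan

    def __call__(self, phi):
        return self.p1 + self.p2 * np.exp(self.p3 * np.cos(np.asarray(phi, float) - self.p4))

    @property
    def preferred_phase_diff(self) -> float:
        """Argmax of the fitted curve (p4 for p2 > 0, opposite for p2 < 0)."""
        return float(self.p4 if self.p2 >= 0 else wrap_angle(self.p4 + np.pi))

    @property
    def params(self):
        return np.array([self.p1, self.p2, self.p3, self.p4])



def _multistart_lsq(residual, starts, lb, ub, what: str):
    """Best finite-cost trust-region solution over a grid of starts.

    Keeps the lowest-cost finite solution; warns when no start formally
    converged (the best point is still returned); raises FitError only
    when every start fails outright.
    """
    import warnings as _warnings
    best, any_success = None, False
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residual, x0, bounds=(lb, ub),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
            )
        except Exception:
            continue
        if not np.isfinite(res.cost):
            continue
        any_success = any_success or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(f"{what} fit did not converge from any start")
    if not any_success:
        _warnings.warn(f"{what} fit: no start reported convergence; "
                       "returning the best point found", stacklevel=3)
    return best


def _sigmoid_model(p, a):
    return p[0] + p[1] * np.tanh((a - p[2]) / (2.0 * p[3]))


def fit_sigmoid(mapping: BinnedMapping) -> SigmoidFit:
    """Nonlinear least squares of F_S to the binned mapping (multi-start)."""
    a, r = mapping.support, mapping.rates
    if a.size < 4:
        raise ValueError("need at least 4 bins for the 4-parameter sigmoid")
    span = max(a.max() - a.min(), 1e-6)
    halfrange = (r.max() - r.min()) / 2.0
    starts = []
    for sign in (1.0, -1.0):
        for p3 in (np.quantile(a, 0.35), np.quantile(a, 0.65)):
            for p4 in (0.1 * span, 0.3 * span):
                starts.append([r.mean(), sign * max(halfrange, 1e-3), p3, p4])
    lb = [-np.inf, -np.inf, -np.inf, 1e-3]
    ub = [np.inf, np.inf, np.inf, np.inf]
    best = _multistart_lsq(lambda p: _sigmoid_model(p, a) - r, starts, lb, ub,
                           "sigmoid")
    p = best.x
    return SigmoidFit(*map(float, p), r2=_r_squared(r, _sigmoid_model(p, a)))


def fit_cosine(mapping: BinnedMapping) -> CosineFit:
    """Least-squares cosine fit, solved in closed form.

    F_C is linear in (p1, p2 cos p3, p2 sin p3); the preferred phase is the
    argmax of the fitted curve and the depth is max-minus-baseline.
    """
    th, r = mapping.support, mapping.rates
    if th.max() - th.min() < np.pi:
        raise ValueError("phase support does not cover the circle")
    design = np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    p1, alpha, beta = coef
    p2 = float(np.hypot(alpha, beta))
    p3 = float(np.arctan2(beta, alpha))
    fit = CosineFit(float(p1), p2, wrap_angle(p3), r2=np.nan)
    fit.r2 = _r_squared(r, fit(th))
    return fit


def _vm_model(p, phi):
    return p[0] + p[1] * np.exp(p[2] * np.cos(phi - p[3]))


def fit_vonmises_rate(mapping: BinnedMapping) -> VonMisesRateFit:
    """Nonlinear least squares of F_D with p3 constrained positive."""
    phi, r = mapping.support, mapping.rates
    if phi.max() - phi.min() < np.pi:
        raise ValueError("phase-difference support does not cover the circle")
    dev = r - r.mean()
    mu0 = float(np.angle(np.sum(dev * np.exp(1j * phi))))
    starts = []
    for p4 in (mu0, wrap_angle(mu0 + np.pi)):
        for p3 in (0.5, 2.0):
            g = np.exp(p3 * np.cos(phi - p4))
            design = np.column_stack([np.ones_like(g), g])
            (p1, p2), *_ = np.linalg.lstsq(design, r, rcond=None)
            starts.append([p1, p2, p3, p4])
    lb = [-np.inf, -np.inf, 1e-3, -2 * np.pi]
    ub = [np.inf, np.inf, 50.0, 2 * np.pi]
    best = _multistart_lsq(lambda p: _vm_model(p, phi) - r, starts, lb, ub,
                           "von Mises rate")
    p = best.x.copy()
    p[3] = wrap_angle(p[3])
    return VonMisesRateFit(*map(float, p), r2=_r_squared(r, _vm_model(p, phi)))


# ---------------------------------------------------------------------------
# joint amplitude x phase binning and the 7-parameter fit
# ---------------------------------------------------------------------------

@dataclass
class JointBinning:
    """Two-stage equal-count partition (amplitude outer, phase inner)."""

    rates: np.ndarray          # (n_ab x n_pb) spikes/s
    amp_support: np.ndarray    # (n_ab,)
    phase_support: np.ndarray  # (n_ab x n_pb) per-cell mean phase
    counts: np.ndarray         # (n_ab x n_pb) spikes per cell
    samples_per_cell: int
    n_truncated: int
    fs: float


def joint_binning(
    amp,
    phase,
    spikes,
    n_ab: int = 8,
    n_pb: int = 16,
    fs: float = 1000.0,
    valid=None,
    min_cell_samples: int = 100,
) -> JointBinning:
    """Joint (amplitude, phase) equal-count rate matrix.

    Samples are sorted by amplitude into ``n_ab`` equal-count bins; within
    each amplitude bin they are further sorted by phase into ``n_pb``
    equal-count cells.
    """
    amp = np.asarray(amp, float)
    phase = np.asarray(phase, float)
    s = np.asarray(getattr(spikes, "x", spikes))
    if not (amp.size == phase.size == s.size):
        raise ValueError("amplitude, phase and spike series differ in length")
    if valid is not None:
        v = np.asarray(valid, bool)
        amp, phase, s = amp[v], phase[v], s[v]
    cell = n_ab * n_pb
    n_t = (amp.size // cell) * cell
    per_cell = n_t // cell
    if per_cell < min_cell_samples:
        raise ValueError(
            f"insufficient samples per cell ({per_cell} < {min_cell_samples})"
        )
    amp, phase, s = amp[:n_t], phase[:n_t], s[:n_t]
    order_a = np.argsort(amp, kind="stable")
    per_row = n_t // n_ab
    amp_rows = amp[order_a].reshape(n_ab, per_row)
    ph_rows = phase[order_a].reshape(n_ab, per_row)
    s_rows = s[order_a].reshape(n_ab, per_row)
    rates = np.empty((n_ab, n_pb))
    counts = np.empty((n_ab, n_pb))
    ph_support = np.empty((n_ab, n_pb))
    for i in range(n_ab):
        order_p = np.argsort(ph_rows[i], kind="stable")
        pc = ph_rows[i][order_p].reshape(n_pb, per_cell)
        sc = s_rows[i][order_p].reshape(n_pb, per_cell)
        counts[i] = sc.sum(axis=1)
        rates[i] = counts[i] * fs / per_cell
        ph_support[i] = pc.mean(axis=1)
    return JointBinning(
        rates=rates,
        amp_support=amp_rows.mean(axis=1),
        phase_support=ph_support,
        counts=counts,
        samples_per_cell=per_cell,
        n_truncated=n_t,
        fs=fs,
    )


@dataclass
class BetaRateFit:
    """7-parameter joint beta-to-rate fit F_B(a, theta).

    Components: ``r_amp(a) = p1 + p2 tanh((a-p3)/(2 p4))``,
    ``r_phase(theta) = cos(theta - p7)`` (unit cosine), and
    ``w_amp(a) = p5 a + p6 a^2`` so that
    F_B = r_amp + w_amp * r_phase identically (b1 = p5, b2 = p6).
    """

    p: np.ndarray  # length 7
    r2: float = np.nan

    def __call__(self, a, theta):
        return self.r_amp(a) + self.w_amp(a) * self.r_phase(theta)

    def r_amp(self, a):
        p = self.p
        return p[0] + p[1] * np.tanh((np.asarray(a, float) - p[2]) / (2.0 * p[3]))

    def r_phase(self, theta):
        return np.cos(np.asarray(theta, float) - self.p[6])

    def w_amp(self, a):
        a = np.asarray(a, float)
        return self.p[4] * a + self.p[5] * a**2

    @property
    def b1(self) -> float:
        return float(self.p[4])

    @property
    def b2(self) -> float:
        return float(self.p[5])

    @property
    def phase_depth_at_mean(self) -> float:
        """Phase-modulation depth at the mean (unit) amplitude: p5 + p6."""
        return float(self.p[4] + self.p[5])


def _beta_model(p, a, th):
    return (
        p[0] + p[1] * np.tanh((a - p[2]) / (2.0 * p[3]))
        + (p[4] * a + p[5] * a**2) * np.cos(th - p[6])
    )


def fit_beta_rate(joint: JointBinning) -> BetaRateFit:
    """Least squares of F_B over all (amplitude, phase) cells."""
    n_ab, n_pb = joint.rates.shape
    if n_ab < 2:
        raise ValueError("rank-deficient design: need >= 2 amplitude bins")
    a = np.repeat(joint.amp_support, n_pb)
    th = joint.phase_support.ravel()
    r = joint.rates.ravel()
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite rates in joint matrix")

    # warm start: sigmoid on row means, phase angle from row-wise harmonics
    row_mean = joint.rates.mean(axis=1)
    amp_map = BinnedMapping(
        "amp", joint.amp_support, row_mean,
        joint.counts.sum(axis=1), n_ab, joint.samples_per_cell * n_pb,
        joint.n_truncated, joint.n_truncated, joint.fs,
    )
    sig = fit_sigmoid(amp_map)
    zsum = 0.0
    depth = np.empty(n_ab)
    ang = np.empty(n_ab)
    for i in range(n_ab):
        th_i = joint.phase_support[i]
        dev = joint.rates[i] - joint.rates[i].mean()
        design = np.column_stack([np.cos(th_i), np.sin(th_i)])
        (al, be), *_ = np.linalg.lstsq(design, dev, rcond=None)
        depth[i] = np.hypot(al, be)
        ang[i] = np.arctan2(be, al)
        zsum += depth[i] * np.exp(1j * ang[i])
    p7 = float(np.angle(zsum))
    # signed depth per row relative to p7, then quadratic weights
    sdepth = depth * np.cos(ang - p7)
    design = np.column_stack([joint.amp_support, joint.amp_support**2])
    (p5, p6), *_ = np.linalg.lstsq(design, sdepth, rcond=None)

    starts = [
        [sig.p1, sig.p2, sig.p3, sig.p4, p5, p6, p7],
        [sig.p1, sig.p2, sig.p3, sig.p4, -p5, -p6, wrap_angle(p7 + np.pi)],
        [r.mean(), (r.max() - r.min()) / 2, 1.0, 0.25, 0.0, 0.0, 0.0],
    ]
    lb = [-np.inf, -np.inf, -np.inf, 1e-3, -np.inf, -np.inf, -2 * np.pi]
    ub = [np.inf] * 6 + [2 * np.pi]
    best = _multistart_lsq(lambda p: _beta_model(p, a, th) - r, starts, lb, ub,
                           "joint beta-to-rate")
    p = best.x.copy()
    # canonical form: w_amp positive at the mean amplitude
    if p[4] + p[5] < 0:
        p[4], p[5], p[6] = -p[4], -p[5], wrap_angle(p[6] + np.pi)
    p[6] = wrap_angle(p[6])
    return BetaRateFit(p=p, r2=_r_squared(r, _beta_model(p, a, th)))


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    x,
    spikes,
    n_bins: int = DEFAULT_N_BINS,
    n_perm: int = 1000,
    seed: int = 0,
    fs: float = 1000.0,
    valid=None,
    min_shift_s: float = 1.0,
) -> float:
    """Randomized permutation test of rate dependence on a conditioning series.

    Statistic: across-bin variance of the equal-count binned rates.  The
    null is built by circularly rotating the spike vector by uniform random
    offsets of at least ``min_shift_s`` (preserving spike autocorrelation
    while destroying the alignment to ``x``).  Returns
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x = np.asarray(x, float)
    s_full = np.asarray(getattr(spikes, "x", spikes)).astype(np.int8)
    if s_full.sum() == 0:
        raise ValueError("zero spikes")
    v = np.ones(x.size, bool) if valid is None else np.asarray(valid, bool)

    xv = x[v]
    n_t = (xv.size // n_bins) * n_bins
    per = n_t // n_bins
    order = np.argsort(xv[:n_t], kind="stable")

    def statistic(s_vec):
        sv = s_vec[v][:n_t]
        counts = sv[order].reshape(n_bins, per).sum(axis=1)
        rates = counts * fs / per
        return float(np.var(rates))

    obs = statistic(s_full)
    rng = np.random.default_rng(seed)
    min_shift = int(min_shift_s * fs)
    if s_full.size <= 2 * min_shift:
        raise ValueError("series too short for the minimum rotation")
    shifts = rng.integers(min_shift, s_full.size - min_shift, size=n_perm)
    exceed = sum(statistic(np.roll(s_full, int(k))) >= obs for k in shifts)
    return (1.0 + exceed) / (1.0 + n_perm)


# ---------------------------------------------------------------------------
# split-half / conditioning / frequency profiles
# ---------------------------------------------------------------------------

def trial_sample_mask(
    trials: pd.DataFrame, n_samples: int, fs: float = 1000.0, parity: str | None = None,
) -> np.ndarray:
    """Boolean mask of samples inside trials (optionally odd/even trials only).

    Trials are numbered from 1 in table order; ``parity='odd'`` keeps
    trials 1, 3, 5, ...  Each trial spans ``t_center_on`` to
    ``t_reward_off``.
    """
    mask = np.zeros(n_samples, dtype=bool)
    for pos, (_, tr) in enumerate(trials.iterrows(), start=1):
        if parity == "odd" and pos % 2 == 0:
            continue
        if parity == "even" and pos % 2 == 1:
            continue
        i0 = int(np.clip(round(tr.t_center_on * fs / 1000.0), 0, n_samples))
        i1 = int(np.clip(round(tr.t_reward_off * fs / 1000.0), 0, n_samples))
        mask[i0:i1] = True
    return mask


def split_half_fits(
    x,
    spikes,
    trials: pd.DataFrame,
    fit_fn=fit_sigmoid,
    n_bins: int = DEFAULT_N_BINS,
    fs: float = 1000.0,
    valid=None,
    name: str = "x",
):
    """Fit the mapping independently on odd and on even trials.

    Returns ``{"odd": (mapping, fit), "even": (mapping, fit)}``.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials for a split-half design")
    x = np.asarray(x, float)
    n = x.size
    base = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    out = {}
    for parity in ("odd", "even"):
        m = base & trial_sample_mask(trials, n, fs, parity)
        if not np.any(m):
            raise ValueError(f"empty {parity}-trial half")
        mapping = equal_count_binning(x, spikes, n_bins, fs, valid=m, name=name)
        out[parity] = (mapping, fit_fn(mapping))
    return out


def remapping_correlation(bc1, bc2, mc1, mc2) -> dict:
    """Within- vs cross-task correlation of a per-unit parameter vector.

    Arguments are equal-length arrays of one fitted parameter per unit for
    the four disjoint datasets (odd/even trials of each task).
    """
    bc1, bc2, mc1, mc2 = (np.asarray(v, float) for v in (bc1, bc2, mc1, mc2))
    corr = lambda u, w: float(np.corrcoef(u, w)[0, 1])
    within = (corr(bc1, bc2) + corr(mc1, mc2)) / 2.0
    cross = (corr(bc1, mc1) + corr(bc1, mc2) + corr(bc2, mc1) + corr(bc2, mc2)) / 4.0
    return {"within": within, "cross": cross}


def condition_mask(
    condition,
    n_samples: int,
    trials: pd.DataFrame | None = None,
    amplitude=None,
    fs: float = 1000.0,
) -> np.ndarray:
    """Boolean sample mask for a conditioning specification.

    ``("target", k)`` — samples of the movement period of trials toward
    target ``k``; ``("stage", name)`` — one of ``move_to_center``,
    ``move_to_target``, ``reward``; ``("amp_quartile", q)`` — quartile
    ``q`` in 0..3 of the amplitude distribution (equal-count split).
    """
    kind, value = condition
    if kind == "amp_quartile":
        if amplitude is None:
            raise ValueError("amplitude series required for amplitude quartiles")
        a = np.asarray(amplitude, float)
        lo, hi = np.quantile(a, [value / 4.0, (value + 1) / 4.0])
        m = (a >= lo) & (a <= hi if value == 3 else a < hi)
        return m
    if trials is None:
        raise ValueError("trial table required for target/stage conditions")
    mask = np.zeros(n_samples, dtype=bool)
    windows = {
        "move_to_center": ("t_center_on", "t_center_enter"),
        "move_to_target": ("t_go", "t_target_enter"),
        "reward": ("t_reward_on", "t_reward_off"),
    }
    if kind == "stage":
        c0, c1 = windows[value]
        sub = trials
    elif kind == "target":
        c0, c1 = windows["move_to_target"]
        sub = trials[trials["target_id"] == value]
    else:
        raise ValueError(f"unknown condition kind {kind!r}")
    for a, b in zip(sub[c0].to_numpy(), sub[c1].to_numpy()):
        i0 = int(np.clip(round(a * fs / 1000.0), 0, n_samples))
        i1 = int(np.clip(round(b * fs / 1000.0), 0, n_samples))
        mask[i0:i1] = True
    if not np.any(mask):
        raise ValueError(f"empty condition: {condition!r}")
    return mask


def conditional_mapping(
    x,
    spikes,
    condition,
    fit_fn,
    trials: pd.DataFrame | None = None,
    amplitude=None,
    n_bins: int = DEFAULT_N_BINS,
    fs: float = 1000.0,
    valid=None,
):
    """Restrict samples to a condition, then bin and fit."""
    x = np.asarray(x, float)
    m = condition_mask(condition, x.size, trials, amplitude, fs)
    if valid is not None:
        m = m & np.asarray(valid, bool)
    if not np.any(m):
        raise ValueError(f"empty condition: {condition!r}")
    mapping = equal_count_binning(x, spikes, n_bins, fs, valid=m)
    return mapping, fit_fn(mapping)


def frequency_profile(
    signal,
    spikes,
    freqs,
    fs: float = 1000.0,
    n_bins: int = DEFAULT_N_BINS,
) -> pd.DataFrame:
    """Amplitude- and phase-mapping rate-change ranges per center frequency.

    For each frequency the signal is filtered and normalized, then the
    amplitude-to-rate (sigmoid) and phase-to-rate (cosine) mappings are
    fitted; the reported range is the fitted curve's max minus min over the
    observed support.  Fit failures are recorded per frequency.
    """
    rows = []
    for f in np.asarray(freqs, float):
        rec = {"freq": float(f), "amp_range": np.nan, "phase_range": np.nan,
               "error": ""}
        try:
            sig = spectral.normalize_amplitude(
                spectral.filter_signal(np.asarray(signal, float), f, fs=fs)
            )
            am = equal_count_binning(sig.amplitude, spikes, n_bins, fs,
                                     valid=sig.valid, name="amplitude")
            s = fit_sigmoid(am)
            rec["amp_range"] = float(abs(s(am.support[-1]) - s(am.support[0])))
            pm = equal_count_binning(sig.phase, spikes, n_bins, fs,
                                     valid=sig.valid, name="phase")
            c = fit_cosine(pm)
            rec["phase_range"] = float(2.0 * c.p2)
        except (FitError, ValueError) as exc:
            rec["error"] = str(exc)
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# external tuning (trial/target components)
# ---------------------------------------------------------------------------

@dataclass
class ExternalTuning:
    """Trial- and target-related rate components learned from training data.

    ``r_baseline`` is the global mean rate; ``r_trial`` is the go-cue-locked
    PSTH deviation from baseline; ``r_target`` maps target id to the mean
    rate deviation (beyond baseline + trial component) during the movement
    period toward that target.
    """

    r_baseline: float
    trial_window_ms: tuple
    r_trial: np.ndarray           # deviation trace over the trial window
    r_target: dict                # target_id -> deviation (spikes/s)
    fs: float = 1000.0

    def predict(self, trials: pd.DataFrame, n_samples: int) -> np.ndarray:
        """Predicted instantaneous rate = sum of learned components."""
        rate = np.full(n_samples, self.r_baseline, dtype=float)
        lo = int(round(self.trial_window_ms[0] * self.fs / 1000.0))
        for _, tr in trials.iterrows():
            i_go = int(round(tr.t_go * self.fs / 1000.0))
            i0 = i_go + lo
            i1 = i0 + self.r_trial.size
            s0, s1 = max(i0, 0), min(i1, n_samples)
            rate[s0:s1] += self.r_trial[s0 - i0: s0 - i0 + (s1 - s0)]
            j0 = int(round(tr.t_go * self.fs / 1000.0))
            j1 = int(round(tr.t_target_enter * self.fs / 1000.0))
            rate[j0:j1] += self.r_target.get(int(tr.target_id), 0.0)
        return np.clip(rate, 0.0, None)


def external_tuning(
    spikes,
    trials: pd.DataFrame,
    window_ms=(-1000.0, 3000.0),
    smooth_ms: float = 100.0,
    fs: float = 1000.0,
) -> ExternalTuning:
    """Learn r_baseline, r_trial and r_target from a training dataset."""
    if trials is None or len(trials) == 0:
        raise ValueError("trial labels missing")
    s = np.asarray(getattr(spikes, "x", spikes))
    r_baseline = float(s.mean() * fs)
    _, trial_rate = spectral.psth(
        s, trials["t_go"].to_numpy(), window_ms, fs, smooth_ms=smooth_ms
    )
    r_trial = trial_rate - r_baseline

    model = ExternalTuning(r_baseline, tuple(window_ms), r_trial, {}, fs)
    base_pred = model.predict(trials, s.size)
    r_target = {}
    for k, g in trials.groupby("target_id"):
        m = condition_mask(("target", int(k)), s.size, trials, fs=fs)
        r_target[int(k)] = float(s[m].mean() * fs - base_pred[m].mean())
    model.r_target = r_target
    return model


def evaluate_rate_prediction(
    predicted_rate,
    spikes,
    n_bins: int = DEFAULT_N_BINS,
    fs: float = 1000.0,
    valid=None,
):
    """Predicted-rate-to-measured-rate mapping with slope and r^2.

    Equal-count bins of the predicted rate; measured rate per bin; least
    squares line of measured on predicted.  Returns
    ``(mapping, slope, r2)``.
    """
    mapping = equal_count_binning(predicted_rate, spikes, n_bins, fs,
                                  valid=valid, name="predicted_rate")
    x, y = mapping.support, mapping.rates
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) predicted rate")
    slope, intercept = np.polyfit(x, y, 1)
    r2 = _r_squared(y, slope * x + intercept)
    return mapping, float(slope), float(r2)
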