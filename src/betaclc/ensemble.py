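"""Ensemble-level consequences of the fitted beta-to-rate mappings.

Heterogeneous amplitude-to-rate sigmoids across an ensemble intersect at
*crossover* amplitudes where two units exchange their spike-rate rank.
The full set of pairwise crossovers partitions the amplitude axis into
intervals, each indexed by one rank-order state (the permutation of units
by descending model-implied rate).  The phase-to-rate mappings likewise
impose a probabilistic spike-*timing* order within the beta cycle: a
preferred phase maps to a lag (ms) relative to the beta trough, and for
pairs of units the within-cycle firing order can be counted directly from
spike trains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .macro import wrap_angle
from .mappings import CosineFit, SigmoidFit
from .spectral import AnalyticSignal

__all__ = [
    "CrossoverSet",
    "RankOrderStateSequence",
    "sigmoid_crossovers",
    "rank_order_states",
    "n_rank_permutations",
    "preferred_phase_to_lag",
    "timing_table",
    "first_spiker_fraction",
]

#: phase of the oscillation trough under the package phase convention
#: (phase 0 at the peak of the band-passed real signal)
THETA_TROUGH = -np.pi

GRID_POINTS = 10_000
DEDUPE_TOL = 1e-4


@dataclass
class CrossoverSet:
    """Amplitudes where two full sigmoid curves (baselines included) intersect."""

    pair: tuple
    crossovers: np.ndarray  # sorted ascending, deduplicated
    domain: tuple


def n_rank_permutations(n_units: int) -> int:
    """Number of possible rank orderings of an ensemble: n!."""
    return math.factorial(n_units)


def sigmoid_crossovers(
    fit_i: SigmoidFit,
    fit_j: SigmoidFit,
    domain=(0.0, 3.0),
    pair=(0, 1),
    grid_points: int = GRID_POINTS,
    tol: float = DEDUPE_TOL,
) -> CrossoverSet:
    """Roots of F_i - F_j on a finite amplitude domain.

    Sign changes on a dense grid are refined by bisection (Brent); an empty
    set is a valid outcome (no overlap of amplitude-to-rate functions, as
    when baseline differences exceed the combined modulation ranges).
    """
    lo, hi = float(domain[0]), float(domain[1])
    if not np.isfinite([lo, hi]).all() or hi <= lo:
        raise ValueError("domain must be a finite increasing interval")
    a = np.linspace(lo, hi, grid_points)
    diff = fit_i(a) - fit_j(a)
    roots = []
    sgn = np.sign(diff)
    for k in np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]:
        roots.append(optimize.brentq(lambda v: fit_i(v) - fit_j(v), a[k], a[k + 1]))
    roots.extend(a[np.nonzero(diff == 0)[0]])
    roots = np.sort(np.asarray(roots, float))
    keep = []
    for r in roots:
        if not keep or r - keep[-1] > tol:
            keep.append(r)
    keep = np.asarray(keep)
    # verify each crossover
    if keep.size:
        resid = np.abs(fit_i(keep) - fit_j(keep))
        keep = keep[resid < 1e-6 * max(1.0, np.abs(fit_i(keep)).max())]
    return CrossoverSet(pair=pair, crossovers=keep, domain=(lo, hi))


@dataclass
class RankOrderStateSequence:
    """Amplitude intervals with the unit permutation (descending rate) per interval."""

    intervals: list   # [(lo, hi), ...] partitioning the domain
    permutations: list  # tuple of unit indices per interval, rate-descending
    unit_ids: list

    @property
    def n_states(self) -> int:
        return len({p for p in self.permutations})

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)


def rank_order_states(
    fits: list,
    domain=(0.0, 3.0),
    unit_ids=None,
    tol: float = DEDUPE_TOL,
) -> RankOrderStateSequence:
    """Rank-order state sequence induced by an ensemble of sigmoid fits.

    All pairwise crossovers become interval boundaries; within each
    interval the units are ranked by descending fitted rate (evaluated at
    the interval midpoint); identical adjacent states are collapsed.
    """
    n = len(fits)
    if n < 2:
        raise ValueError("need at least 2 units")
    if unit_ids is None:
        unit_ids = list(range(n))
    bounds = [float(domain[0]), float(domain[1])]
    for i in range(n):
        for j in range(i + 1, n):
            cs = sigmoid_crossovers(fits[i], fits[j], domain, pair=(i, j), tol=tol)
            bounds.extend(cs.crossovers.tolist())
    bounds = np.sort(np.asarray(bounds))
    merged = [bounds[0]]
    collided = False
    for b in bounds[1:]:
        if b - merged[-1] > tol:
            merged.append(b)
        elif b != merged[-1]:
            collided = True
    if collided:
        warnings.warn("crossover collision below resolution; boundaries merged",
                      stacklevel=2)
    merged = np.asarray(merged)
    if merged[-1] < domain[1]:
        merged[-1] = domain[1]

    intervals, perms = [], []
    for lo, hi in zip(merged[:-1], merged[1:]):
        mid = (lo + hi) / 2.0
        rates = np.array([f(mid) for f in fits])
        # descending rate; ties broken by unit index for determinism
        perm = tuple(np.lexsort((np.arange(n), -rates)))
        if perms and perm == perms[-1]:
            intervals[-1] = (intervals[-1][0], float(hi))
        else:
            intervals.append((float(lo), float(hi)))
            perms.append(perm)
    return RankOrderStateSequence(intervals=intervals, permutations=perms,
                                  unit_ids=list(unit_ids))


def preferred_phase_to_lag(fit: CosineFit, v0: float) -> float:
    """Most-probable spike time (ms) relative to the beta trough.

    The preferred phase p3 is converted to a lag within one cycle:
    ``wrap(p3 - theta_trough) / (2 pi) * (1000 / v0)``, in [0, period).
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    period_ms = 1000.0 / v0
    frac = np.mod(fit.p3 - THETA_TROUGH, 2.0 * np.pi) / (2.0 * np.pi)
    return float(frac * period_ms)


def timing_table(fits: dict, v0: float) -> pd.DataFrame:
    """Per-unit preferred phase and trough-relative lag, sorted by lag."""
    rows = [
        {"unit_id": uid, "preferred_phase": float(wrap_angle(f.p3)),
         "lag_ms": preferred_phase_to_lag(f, v0)}
        for uid, f in fits.items()
    ]
    df = pd.DataFrame(rows).sort_values("lag_ms").reset_index(drop=True)
    df["order"] = np.arange(len(df))
    return df


def _cycle_bounds(analytic: AnalyticSignal) -> np.ndarray:
    """Trough-to-trough cycle boundaries located at phase wraps."""
    th = np.angle(analytic.z)
    wraps = np.nonzero(np.diff(th) < -np.pi)[0] + 1
    return wraps


def first_spiker_fraction(
    train_a,
    train_b,
    analytic: AnalyticSignal,
    amplitude_deciles: bool = False,
):
    """Fraction of single-spike cycles in which unit a fires before unit b.

    Cycles are trough-to-trough segments of the meso-scale analytic signal
    (boundaries at phase wraps); only cycles where each unit fires exactly
    once are counted, and cycles where the two spikes share a 1-ms bin are
    excluded (their count is reported).  With ``amplitude_deciles=True``
    per-cycle mean amplitudes stratify the qualifying cycles into deciles
    and a per-decile fraction is returned as well.

    Returns a dict with ``fraction``, ``n_cycles``, ``n_ties`` and
    optionally ``decile_fractions``.
    """
    xa = np.asarray(getattr(train_a, "x", train_a))
    xb = np.asarray(getattr(train_b, "x", train_b))
    bounds = _cycle_bounds(analytic)
    amp = np.abs(analytic.z)
    valid = analytic.valid

    ca = np.cumsum(np.concatenate([[0], xa]))
    cb = np.cumsum(np.concatenate([[0], xb]))
    firsts, amps = [], []
    n_ties = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if not valid[lo:hi].all():
            continue
        if ca[hi] - ca[lo] != 1 or cb[hi] - cb[lo] != 1:
            continue
        ia = lo + int(np.argmax(xa[lo:hi]))
        ib = lo + int(np.argmax(xb[lo:hi]))
        if ia == ib:
            n_ties += 1
            continue
        firsts.append(ia < ib)
        amps.append(amp[lo:hi].mean())
    if not firsts:
        raise ValueError("zero qualifying cycles")
    firsts = np.asarray(firsts)
    out = {
        "fraction": float(firsts.mean()),
        "n_cycles": int(firsts.size),
        "n_ties": int(n_ties),
    }
    if amplitude_deciles:
        amps = np.asarray(amps)
        edges = np.quantile(amps, np.linspace(0, 1, 11))
        decile = np.clip(np.searchsorted(edges, amps, side="right") - 1, 0, 9)
        out["decile_fractions"] = np.array([
            firsts[decile == d].mean() if np.any(decile == d) else np.nan
            for d in range(10)
        ])
    return out
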