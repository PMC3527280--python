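"""Multivariate spike-rate prediction from multichannel beta coefficients.

Each 1-ms sample of the band-filtered array yields a complex vector x
(one coefficient per channel: modulus = beta amplitude, argument = beta
phase).  Two *augmented* complex Gaussian distributions are fitted — a
baseline density p_BASE over all samples and a spike-triggered density
p_ST over the samples at spike times — using the augmented vector
x_B = [x; conj(x)] with mean mu_B and 2N x 2N augmented covariance R_B
(block structure [[Gamma, C], [conj(C), conj(Gamma)]], capturing both the
covariance and the pseudo-covariance of an improper complex signal):

    p(x) = beta exp(-1/2 (x_B - mu_B)^H R_B^{-1} (x_B - mu_B)),
    beta = 1 / (pi^N sqrt(det R_B)).

The per-sample log-likelihood ratio L(x) = log[p_ST(x) / p_BASE(x)] is
calibrated to spike rate through the 4-parameter sigmoid of the mappings
module (equal-count binning of L vs rate), giving the predicted
instantaneous rate R_EST(x) = F_S(L(x)).  Log-densities are evaluated via
the exact isomorphism to the 2N-dimensional real Gaussian on
[Re x; Im x], whose covariance is M R_B M^H with M = 1/2 [[I, I],
[-iI, iI]]; a Cholesky factorization of that real covariance provides
numerically robust solves and log-determinants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from . import mappings as mp
from . import spectral

__all__ = [
    "ComplexGaussianModel",
    "RatePredictionResult",
    "filter_channels",
    "fit_complex_gaussian",
    "loglik_ratio_series",
    "calibrate_and_predict",
    "evaluate_prediction",
    "nested_channel_subsets",
    "channel_subset_analysis",
    "cross_task_transfer",
]

DEFAULT_SHRINKAGE = 1e-4


@dataclass
class ComplexGaussianModel:
    """Augmented complex Gaussian over N_channel beta coefficients."""

    channels: list
    mu_b: np.ndarray     # (2N,) complex augmented mean
    r_b: np.ndarray      # (2N x 2N) complex augmented covariance
    shrinkage: float

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    # -- real-composite machinery -------------------------------------------
    def _real_moments(self):
        n = self.n_channels
        mu_y = np.concatenate([self.mu_b[:n].real, self.mu_b[:n].imag])
        m = _composite_matrix(n)
        sigma_y = (m @ self.r_b @ m.conj().T).real
        return mu_y, sigma_y

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Log p(x) for samples x of shape (N,) or (N, n_samples)."""
        x = np.atleast_2d(np.asarray(x, complex).T).T
        if x.shape[0] != self.n_channels:
            raise ValueError("channel count mismatch")
        mu_y, sigma_y = self._real_moments()
        y = np.vstack([x.real, x.imag]) - mu_y[:, None]
        chol = linalg.cholesky(sigma_y, lower=True)
        w = linalg.solve_triangular(chol, y, lower=True)
        logdet_y = 2.0 * np.sum(np.log(np.diag(chol)))
        n = self.n_channels
        const = -n * np.log(2.0 * np.pi) - 0.5 * logdet_y
        out = const - 0.5 * np.sum(w * w, axis=0)
        return out if out.size > 1 else float(out[0])

    def log_density_complex_form(self, x: np.ndarray) -> np.ndarray:
        """Direct evaluation of the augmented complex-Gaussian formula.

        Kept as the algebraically explicit route (log beta minus the
        quadratic form in R_B); agrees with :meth:`log_density` exactly.
        """
        x = np.atleast_2d(np.asarray(x, complex).T).T
        xb = np.vstack([x, x.conj()]) - self.mu_b[:, None]
        n = self.n_channels
        sign, logdet = np.linalg.slogdet(self.r_b)
        sol = np.linalg.solve(self.r_b, xb)
        quad = np.real(np.sum(xb.conj() * sol, axis=0))
        out = -n * np.log(np.pi) - 0.5 * logdet.real - 0.5 * quad
        return out if out.size > 1 else float(out[0])


def _composite_matrix(n: int) -> np.ndarray:
    """M with [Re x; Im x] = M [x; conj(x)]."""
    eye = np.eye(n)
    return 0.5 * np.block([[eye, eye], [-1j * eye, 1j * eye]])


def filter_channels(
    data: np.ndarray,
    v0: float = 28.0,
    fs: float = 1000.0,
    normalize: bool = True,
):
    """Band-filter every channel; returns (complex matrix, joint valid mask).

    With ``normalize=True`` each channel's amplitude is scaled to unit
    mean over its valid samples before model fitting.
    """
    data = np.asarray(data, float)
    rows, valid = [], None
    for c in range(data.shape[0]):
        sig = spectral.filter_signal(data[c], v0, fs=fs)
        if normalize:
            sig = spectral.normalize_amplitude(sig)
        rows.append(sig.z)
        valid = sig.valid if valid is None else (valid & sig.valid)
    return np.vstack(rows), valid


def fit_complex_gaussian(
    samples: np.ndarray,
    channels=None,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> ComplexGaussianModel:
    """Fit mu_B and R_B from complex sample vectors (N_channel x n_samples).

    The augmented covariance gets diagonal shrinkage
    ``lambda * (trace(R_B) / 2N) * I`` so spike-triggered fits with few
    samples stay well conditioned; the block structure holds by
    construction.
    """
    x = np.asarray(samples, complex)
    if x.ndim != 2:
        raise ValueError("expected (N_channel x n_samples) complex samples")
    n, m = x.shape
    if m < 10 * n:
        raise ValueError(f"need >= {10 * n} samples for {n} channels, got {m}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite inputs")
    if channels is None:
        channels = list(range(n))
    xb = np.vstack([x, x.conj()])
    mu_b = xb.mean(axis=1)
    d = xb - mu_b[:, None]
    r_b = (d @ d.conj().T) / m
    if shrinkage > 0:
        r_b = r_b + shrinkage * (np.trace(r_b).real / (2 * n)) * np.eye(2 * n)
    return ComplexGaussianModel(list(channels), mu_b, r_b, shrinkage)


def loglik_ratio_series(
    model_st: ComplexGaussianModel,
    model_base: ComplexGaussianModel,
    signals: np.ndarray,
) -> np.ndarray:
    """Per-sample L(x) = log p_ST(x) - log p_BASE(x)."""
    if model_st.channels != model_base.channels:
        raise ValueError("models were fitted on different channel lists")
    ls = model_st.log_density(signals)
    lb = model_base.log_density(signals)
    return np.asarray(ls) - np.asarray(lb)


@dataclass
class RatePredictionResult:
    """L-to-rate calibration and its application to test data."""

    l_sigmoid: mp.SigmoidFit
    l_mapping: mp.BinnedMapping
    l_test: np.ndarray
    r_est: np.ndarray

    @property
    def fs(self) -> float:
        return self.l_mapping.fs


def calibrate_and_predict(
    l_train: np.ndarray,
    spikes_train,
    l_test: np.ndarray,
    n_bins: int = mp.DEFAULT_N_BINS,
    fs: float = 1000.0,
    valid_train=None,
) -> RatePredictionResult:
    """Equal-count L-to-rate mapping, sigmoid fit, application to test L."""
    l_map = mp.equal_count_binning(l_train, spikes_train, n_bins, fs,
                                   valid=valid_train, name="loglik_ratio")
    sig = mp.fit_sigmoid(l_map)
    r_est = np.clip(sig(np.asarray(l_test, float)), 0.0, None)
    return RatePredictionResult(l_sigmoid=sig, l_mapping=l_map,
                                l_test=np.asarray(l_test, float), r_est=r_est)


def evaluate_prediction(
    result,
    spikes_test,
    n_bins: int = mp.DEFAULT_N_BINS,
    fs: float = 1000.0,
    valid=None,
):
    """Estimated-rate-to-measured-rate mapping with slope and r^2.

    ``result`` may be a :class:`RatePredictionResult` or a bare predicted
    rate series.  Returns ``(mapping, slope, r2)``.
    """
    r_est = getattr(result, "r_est", result)
    return mp.evaluate_rate_prediction(r_est, spikes_test, n_bins, fs, valid=valid)


def nested_channel_subsets(coords_mm: np.ndarray, anchor: int = 0,
                           sizes=(4, 16, 36, 64)) -> dict:
    """Nested square channel groups around a spike electrode.

    Channels are ranked by Chebyshev distance from the anchor electrode so
    the groups grow as concentric squares (4, 16, 36, 64 on an 8x8 grid).
    """
    coords = np.asarray(coords_mm, float)
    d = np.max(np.abs(coords - coords[anchor]), axis=1)
    order = np.lexsort((np.arange(len(coords)), d))
    out = {}
    for s in sizes:
        if s > len(coords):
            raise ValueError(f"subset size {s} exceeds array ({len(coords)})")
        if s == 0:
            raise ValueError("empty subset")
        out[s] = np.sort(order[:s])
    return out


def _fit_predict_eval(z_train, valid_train, spikes_train,
                      z_test, valid_test, spikes_test,
                      shrinkage=DEFAULT_SHRINKAGE, n_bins=mp.DEFAULT_N_BINS,
                      fs=1000.0):
    # densities come from the first half of the training data, the
    # L-to-rate calibration from the second (a fresh block), so the
    # calibration learns the out-of-sample L-rate relation
    s_train = np.asarray(getattr(spikes_train, "x", spikes_train))
    n = z_train.shape[1]
    model_half = np.zeros(n, bool)
    model_half[: n // 2] = True
    calib_half = ~model_half
    st_mask = (s_train > 0) & valid_train & model_half
    base = fit_complex_gaussian(z_train[:, valid_train & model_half],
                                shrinkage=shrinkage)
    st = fit_complex_gaussian(z_train[:, st_mask], shrinkage=shrinkage)
    l_train = loglik_ratio_series(st, base, z_train)
    l_test = loglik_ratio_series(st, base, z_test)
    res = calibrate_and_predict(l_train, spikes_train, l_test, n_bins, fs,
                                valid_train=valid_train & calib_half)
    mapping, slope, r2 = evaluate_prediction(res, spikes_test, n_bins, fs,
                                             valid=valid_test)
    return {
        "result": res, "mapping": mapping, "slope": slope, "r2": r2,
        "measured_range": mapping.rate_range,
    }


def channel_subset_analysis(
    z: np.ndarray,
    valid: np.ndarray,
    spikes_train,
    spikes_test,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    coords_mm: np.ndarray,
    anchor: int = 0,
    sizes=(4, 16, 36, 64),
    shrinkage: float = DEFAULT_SHRINKAGE,
    fs: float = 1000.0,
) -> dict:
    """Full fit/predict/evaluate pipeline per nested channel subset.

    ``z`` is the full filtered (channels x samples) matrix; ``train_mask``
    and ``test_mask`` select disjoint sample sets.  Reports the measured
    -rate range (and slope/r^2) per subset size.
    """
    subsets = nested_channel_subsets(coords_mm, anchor, sizes)
    out = {}
    for s, chan in subsets.items():
        out[s] = _fit_predict_eval(
            z[chan][:, train_mask], valid[train_mask], _mask_spikes(spikes_train, train_mask),
            z[chan][:, test_mask], valid[test_mask], _mask_spikes(spikes_test, test_mask),
            shrinkage=shrinkage, fs=fs,
        )
    return out


def _mask_spikes(spikes, mask):
    x = np.asarray(getattr(spikes, "x", spikes))
    return x[mask]


def cross_task_transfer(
    datasets: dict,
    shrinkage: float = DEFAULT_SHRINKAGE,
    fs: float = 1000.0,
) -> dict:
    """Within- vs cross-task prediction evaluation.

    ``datasets`` maps task label -> dict with ``z`` (channels x samples),
    ``valid``, ``spikes`` and disjoint ``train_mask`` / ``test_mask``.
    Returns records for the four train/test combinations keyed
    ``(train_task, test_task)``; training always uses the train half and
    testing the test half, so within-task numbers are out-of-sample.
    """
    for need in ("MC", "BC"):
        if need not in datasets:
            raise ValueError(f"missing task {need}")
    out = {}
    for tr_task, tr in datasets.items():
        st_mask = (np.asarray(getattr(tr["spikes"], "x", tr["spikes"])) > 0)
        m_train = tr["train_mask"] & tr["valid"]
        idx = np.nonzero(m_train)[0]
        model_half = np.zeros_like(m_train)
        model_half[idx[: idx.size // 2]] = True
        calib_half = m_train & ~model_half
        base = fit_complex_gaussian(tr["z"][:, m_train & model_half],
                                    shrinkage=shrinkage)
        st = fit_complex_gaussian(tr["z"][:, m_train & model_half & st_mask],
                                  shrinkage=shrinkage)
        l_train = loglik_ratio_series(st, base, tr["z"])
        for te_task, te in datasets.items():
            l_test = loglik_ratio_series(st, base, te["z"])
            res = calibrate_and_predict(
                l_train, tr["spikes"], l_test, fs=fs,
                valid_train=calib_half,
            )
            m_test = te["test_mask"] & te["valid"]
            mapping, slope, r2 = evaluate_prediction(
                res, te["spikes"], fs=fs, valid=m_test,
            )
            out[(tr_task, te_task)] = {
                "slope": slope, "r2": r2, "measured_range": mapping.rate_range,
            }
    return out


def model_to_json(model: ComplexGaussianModel, path: str) -> None:
    """Serialize model parameters (complex numbers as [re, im] pairs)."""
    payload = {
        "channels": [int(c) for c in model.channels],
        "shrinkage": model.shrinkage,
        "mu_b": [[z.real, z.imag] for z in model.mu_b],
        "r_b": [[[z.real, z.imag] for z in row] for row in model.r_b],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def model_from_json(path: str) -> ComplexGaussianModel:
    with open(path) as fh:
        payload = json.load(fh)
    mu = np.array([complex(a, b) for a, b in payload["mu_b"]])
    rb = np.array([[complex(a, b) for a, b in row] for row in payload["r_b"]])
    return ComplexGaussianModel(payload["channels"], mu, rb, payload["shrinkage"])
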