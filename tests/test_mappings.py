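"""Equal-count binning, parametric fits, permutation test and conditioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betaclc import mappings as mp
from betaclc import synth

FS = 1000.0


def bernoulli_spikes(rate, rng):
    return (rng.random(rate.size) < np.asarray(rate) / FS).astype(np.uint8)


class TestEqualCountBinning:
    def test_samples_per_bin(self):
        rng = np.random.default_rng(0)
        m = mp.equal_count_binning(rng.random(100), np.zeros(100, np.uint8), 25)
        assert m.samples_per_bin == 4
        assert m.n_truncated == 100

    def test_truncation_floor_rule(self):
        rng = np.random.default_rng(1)
        m = mp.equal_count_binning(rng.random(103), np.zeros(103, np.uint8), 25)
        # oracle: largest integer <= N divisible by n_bins
        assert m.n_truncated == max(k for k in range(104) if k % 25 == 0)
        assert m.n_truncated == 100

    def test_homogeneous_unit_flat_and_conserving(self):
        rng = np.random.default_rng(2)
        n = 250_000
        x = rng.random(n)
        s = bernoulli_spikes(np.full(n, 20.0), rng)
        m = mp.equal_count_binning(x, s, 25)
        se = np.sqrt(20.0 * FS / m.samples_per_bin)
        assert np.all(np.abs(m.rates - 20.0) < 4 * se)
        # conservation is exact
        n_t = m.n_truncated
        assert m.global_rate == pytest.approx(s[:n_t].mean() * FS, abs=1e-12)
        assert np.average(m.rates, weights=np.full(25, m.samples_per_bin)) == \
            pytest.approx(m.global_rate, abs=1e-12)

    def test_support_nondecreasing(self):
        rng = np.random.default_rng(3)
        m = mp.equal_count_binning(rng.standard_normal(10_000),
                                   np.zeros(10_000, np.uint8), 25)
        assert np.all(np.diff(m.support) >= 0)

    def test_too_little_data(self):
        with pytest.raises(ValueError, match="too little"):
            mp.equal_count_binning(np.arange(10.0), np.zeros(10, np.uint8), 25)


class TestSigmoidFit:
    def test_exact_recovery_on_noiseless_bins(self):
        a = np.linspace(0.3, 2.2, 25)
        truth = mp.SigmoidFit(10.0, -4.0, 1.0, 0.2)
        m = mp.BinnedMapping("a", a, truth(a), truth(a) * 4.8, 25, 4800,
                             120_000, 120_000, FS)
        fit = mp.fit_sigmoid(m)
        assert np.allclose(fit.params, truth.params, rtol=1e-6)

    def test_flat_bins_degenerate(self):
        a = np.linspace(0.3, 2.2, 25)
        m = mp.BinnedMapping("a", a, np.full(25, 17.0), np.full(25, 17 * 4.8),
                             25, 4800, 120_000, 120_000, FS)
        fit = mp.fit_sigmoid(m)
        assert abs(fit.p2) < 1e-6
        assert fit.p1 == pytest.approx(17.0, abs=1e-6)

    def test_negative_slope_classified(self, beta300):
        p = synth.TaskParams(r_baseline=20.0, amp_p2=-6.0, amp_p4=0.15)
        tr = synth.generate_spikes(p, None, beta300, seed=40)
        m = mp.equal_count_binning(beta300.amplitude, tr, 25, valid=beta300.valid)
        fit = mp.fit_sigmoid(m)
        assert fit.p2 < 0  # decrease-with-amplitude direction class
        assert fit.p4 > 0

    def test_offset_equivariance(self):
        a = np.linspace(0.3, 2.2, 25)
        truth = mp.SigmoidFit(10.0, -4.0, 1.0, 0.2)
        m1 = mp.BinnedMapping("a", a, truth(a), truth(a), 25, 1, 25, 25, FS)
        m2 = mp.BinnedMapping("a", a, truth(a) + 7.0, truth(a), 25, 1, 25, 25, FS)
        f1, f2 = mp.fit_sigmoid(m1), mp.fit_sigmoid(m2)
        assert f2.p1 - f1.p1 == pytest.approx(7.0, abs=1e-6)
        assert np.allclose(f1.params[1:], f2.params[1:], atol=1e-6)


class TestCosineFit:
    def test_recovery_under_uniform_phase(self):
        rng = np.random.default_rng(4)
        n = 400_000
        th = rng.uniform(-np.pi, np.pi, n)
        s = bernoulli_spikes(20 + 5 * np.cos(th - 1.0), rng)
        fit = mp.fit_cosine(mp.equal_count_binning(th, s, 25))
        assert fit.p1 == pytest.approx(20.0, abs=0.5)
        assert fit.p2 == pytest.approx(5.0, abs=0.5)
        assert fit.p3 == pytest.approx(1.0, abs=0.1)

    def test_phase_independent_depth_near_zero(self):
        rng = np.random.default_rng(5)
        th = rng.uniform(-np.pi, np.pi, 300_000)
        s = bernoulli_spikes(np.full(th.size, 20.0), rng)
        fit = mp.fit_cosine(mp.equal_count_binning(th, s, 25))
        assert fit.p2 < 1.0

    def test_shift_equivariance(self):
        from betaclc.macro import wrap_angle
        rng = np.random.default_rng(6)
        th = rng.uniform(-np.pi, np.pi, 200_000)
        s = bernoulli_spikes(20 + 5 * np.cos(th - 0.5), rng)
        delta = 1.7
        f0 = mp.fit_cosine(mp.equal_count_binning(th, s, 25))
        f1 = mp.fit_cosine(mp.equal_count_binning(wrap_angle(th + delta), s, 25))
        assert wrap_angle(f1.p3 - f0.p3) == pytest.approx(delta, abs=0.1)
        assert f1.p1 == pytest.approx(f0.p1, abs=0.5)
        assert f1.p2 == pytest.approx(f0.p2, abs=0.5)


class TestVonMisesRateFit:
    def test_recovery_on_generated_data(self):
        rng = np.random.default_rng(7)
        phi = rng.uniform(-np.pi, np.pi, 400_000)
        truth = mp.VonMisesRateFit(2.0, 3.0, 1.5, 0.0)
        s = bernoulli_spikes(truth(phi), rng)
        fit = mp.fit_vonmises_rate(mp.equal_count_binning(phi, s, 25))
        assert fit(np.linspace(-np.pi, np.pi, 50)) == pytest.approx(
            truth(np.linspace(-np.pi, np.pi, 50)), abs=1.5)
        assert fit.p4 == pytest.approx(0.0, abs=0.2)

    def test_flat_data_no_dependence(self):
        rng = np.random.default_rng(8)
        phi = rng.uniform(-np.pi, np.pi, 300_000)
        s = bernoulli_spikes(np.full(phi.size, 10.0), rng)
        m = mp.equal_count_binning(phi, s, 25)
        fit = mp.fit_vonmises_rate(m)
        curve = fit(np.linspace(-np.pi, np.pi, 100))
        # the fitted variation stays within the noise span of the bins
        assert curve.max() - curve.min() <= m.rates.max() - m.rates.min()
        assert fit.r2 < 0.5  # flags "no dependence"

    def test_task_flip_shifts_preferred_difference_by_pi(self, beta300,
                                                         beta300_right):
        from betaclc import macro
        from betaclc.macro import wrap_angle
        pd_ = macro.phase_difference(beta300, beta300_right)
        gt = synth.UnitGroundTruth("u", {
            "BC": synth.TaskParams(r_baseline=20.0, pd_p2=4.0, pd_p3=1.0,
                                   pd_p4=0.4),
            "MC": synth.TaskParams(r_baseline=20.0, pd_p2=4.0, pd_p3=1.0,
                                   pd_p4=wrap_angle(0.4 + np.pi)),
        })
        prefs = {}
        for task in ("BC", "MC"):
            tr = synth.generate_spikes(gt, task, beta300, pd_.phi, seed=41)
            m = mp.equal_count_binning(pd_.phi, tr, 25,
                                       valid=beta300.valid & pd_.valid)
            prefs[task] = mp.fit_vonmises_rate(m).preferred_phase_diff
        assert abs(wrap_angle(prefs["MC"] - prefs["BC"])) == pytest.approx(
            np.pi, abs=0.5)


class TestJointBinningAndBetaFit:
    def test_homogeneous_cells_equal(self):
        rng = np.random.default_rng(10)
        n = 8 * 16 * 1500
        amp = rng.random(n) + 0.5
        th = rng.uniform(-np.pi, np.pi, n)
        s = bernoulli_spikes(np.full(n, 20.0), rng)
        jb = mp.joint_binning(amp, th, s, 8, 16)
        se = np.sqrt(20.0 * FS / jb.samples_per_cell)
        assert np.all(np.abs(jb.rates - 20.0) < 5 * se)

    def test_row_collapse_matches_univariate_amplitude_binning(self):
        rng = np.random.default_rng(11)
        n = 8 * 16 * 1000  # multiple of both partitions
        amp = rng.random(n) + 0.5
        th = rng.uniform(-np.pi, np.pi, n)
        s = bernoulli_spikes(20 + 8 * (amp - 1.0), rng)
        jb = mp.joint_binning(amp, th, s, 8, 16)
        uni = mp.equal_count_binning(amp, s, 8)
        assert np.allclose(jb.rates.mean(axis=1), uni.rates, atol=1e-9)
        assert np.allclose(jb.amp_support, uni.support, atol=1e-12)

    def test_insufficient_cell_samples(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError, match="insufficient"):
            mp.joint_binning(rng.random(5000), rng.random(5000),
                             np.zeros(5000, np.uint8), 8, 16)

    def test_beta_fit_recovery(self):
        rng = np.random.default_rng(13)
        n = 8 * 16 * 3000
        amp = rng.lognormal(0, 0.35, n)
        amp /= amp.mean()
        th = rng.uniform(-np.pi, np.pi, n)
        p = np.array([20.0, -6.0, 1.0, 0.2, 3.0, 1.0, 0.8])
        rate = mp._beta_model(p, amp, th)
        s = bernoulli_spikes(rate, rng)
        fit = mp.fit_beta_rate(mp.joint_binning(amp, th, s, 8, 16))
        # the fitted amplitude component reproduces the true one (the raw
        # p1/p2 offsets trade off when the support does not fully saturate)
        a_grid = np.linspace(0.6, 1.8, 30)
        true_amp = 20.0 - 6.0 * np.tanh((a_grid - 1.0) / 0.4)
        assert np.allclose(fit.r_amp(a_grid), true_amp, atol=1.0)
        assert fit.p[6] == pytest.approx(0.8, abs=0.25)
        # depth at the mean amplitude is the identifiable phase quantity
        assert fit.phase_depth_at_mean == pytest.approx(4.0, abs=0.8)
        assert fit.b1 == fit.p[4] and fit.b2 == fit.p[5]

    def test_null_phase_term_reduces_to_sigmoid(self):
        rng = np.random.default_rng(14)
        n = 8 * 16 * 2000
        amp = rng.lognormal(0, 0.35, n)
        amp /= amp.mean()
        th = rng.uniform(-np.pi, np.pi, n)
        p = np.array([20.0, -6.0, 1.0, 0.2, 0.0, 0.0, 0.0])
        s = bernoulli_spikes(mp._beta_model(p, amp, th), rng)
        jb = mp.joint_binning(amp, th, s, 8, 16)
        fit = mp.fit_beta_rate(jb)
        assert abs(fit.phase_depth_at_mean) < 0.8
        uni = mp.fit_sigmoid(mp.equal_count_binning(amp, s, 25))
        a = np.linspace(0.5, 1.8, 30)
        assert np.allclose(fit.r_amp(a), uni(a), atol=1.0)

    def test_decomposition_identity(self):
        fit = mp.BetaRateFit(p=np.array([20.0, -6.0, 1.0, 0.2, 3.0, 1.0, 0.8]))
        a = np.linspace(0.3, 2.5, 40)
        th = np.linspace(-np.pi, np.pi, 40)
        lhs = fit(a[:, None], th[None, :])
        rhs = fit.r_amp(a)[:, None] + fit.w_amp(a)[:, None] * fit.r_phase(th)[None, :]
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestPermutationTest:
    def test_shift_invariance_of_statistic(self, beta300):
        p = synth.TaskParams(r_baseline=20.0, amp_p2=-6.0)
        tr = synth.generate_spikes(p, None, beta300, seed=42)
        a = beta300.amplitude[beta300.valid]
        s = tr.x[beta300.valid]

        def stat(x, sp):
            m = mp.equal_count_binning(x, sp, 25)
            return np.var(m.rates)

        n_t = (a.size // 25) * 25
        a, s = a[:n_t], s[:n_t]
        k = 40_000
        assert stat(np.roll(a, k), np.roll(s, k)) == pytest.approx(stat(a, s))

    def test_strong_coupling_hits_floor(self, beta300):
        p = synth.TaskParams(r_baseline=20.0, amp_p2=-10.0, amp_p4=0.15)
        tr = synth.generate_spikes(p, None, beta300, seed=43)
        pv = mp.permutation_test(beta300.amplitude, tr, n_perm=200, seed=1,
                                 valid=beta300.valid)
        assert pv == pytest.approx(1.0 / 201.0)

    def test_zero_spikes_rejected(self):
        with pytest.raises(ValueError, match="zero spikes"):
            mp.permutation_test(np.random.default_rng(0).random(10_000),
                                np.zeros(10_000, np.uint8), n_perm=100)

    def test_min_permutations(self):
        with pytest.raises(ValueError, match="n_perm"):
            mp.permutation_test(np.ones(10), np.ones(10, np.uint8), n_perm=10)


class TestSplitHalf:
    def test_duplicated_data_perfect_correlation(self, task_dataset):
        d = task_dataset["BC"]
        sig = d["sig"]
        p = synth.TaskParams(r_baseline=25.0, amp_p2=-8.0, amp_p4=0.15)
        tr = synth.generate_spikes(p, None, sig, seed=44)
        # duplicate trials so odd and even halves see identical data
        t2 = d["trials"].copy()
        dup = (
            d["trials"].loc[d["trials"].index.repeat(2)].reset_index(drop=True))
        halves = mp.split_half_fits(sig.amplitude, tr, dup, mp.fit_sigmoid,
                                    valid=sig.valid)
        f_odd, f_even = halves["odd"][1], halves["even"][1]
        assert np.allclose(f_odd.params, f_even.params, rtol=1e-6)

    def test_same_ground_truth_similar_slopes(self, task_dataset):
        d = task_dataset["BC"]
        sig = d["sig"]
        p = synth.TaskParams(r_baseline=25.0, amp_p2=-8.0, amp_p4=0.15)
        tr = synth.generate_spikes(p, None, sig, seed=45)
        halves = mp.split_half_fits(sig.amplitude, tr, d["trials"],
                                    mp.fit_sigmoid, valid=sig.valid)
        s_odd, s_even = halves["odd"][1].p2, halves["even"][1].p2
        assert np.sign(s_odd) == np.sign(s_even)
        assert s_odd == pytest.approx(s_even, abs=6.0)

    def test_needs_two_trials(self, task_dataset):
        d = task_dataset["BC"]
        with pytest.raises(ValueError, match="2 trials"):
            mp.split_half_fits(d["sig"].amplitude, np.zeros(len(d["sig"].z)),
                               d["trials"].iloc[:1], mp.fit_sigmoid)


class TestConditional:
    def test_amplitude_quartile_gating_monotone_depth(self, beta300):
        # amplitude-gated phase coupling: depth grows across quartiles
        p = synth.TaskParams(r_baseline=20.0, w_b1=2.0, w_b2=4.0,
                             phase_pref=0.5)
        tr = synth.generate_spikes(p, None, beta300, seed=46)
        depths = []
        for q in range(4):
            _, fit = mp.conditional_mapping(
                beta300.phase, tr, ("amp_quartile", q), mp.fit_cosine,
                amplitude=beta300.amplitude, valid=beta300.valid)
            depths.append(fit.p2)
        assert np.all(np.diff(depths) > 0)

    def test_target_conditioned_baseline_follows_tuning(self, task_dataset):
        d = task_dataset["BC"]
        sig = d["sig"]
        p = synth.TaskParams(r_baseline=20.0, target_pref=3, target_depth=8.0)
        tr = synth.generate_spikes(p, None, sig, trials=d["trials"], seed=47)
        n = len(sig.z)
        rates = {}
        for k in range(1, 9):
            m = mp.condition_mask(("target", k), n, d["trials"], fs=FS)
            rates[k] = tr.x[m].mean() * FS
        expected = {k: 20.0 + 8.0 * np.cos(2 * np.pi * (k - 3) / 8.0)
                    for k in rates}
        meas = np.array([rates[k] for k in range(1, 9)])
        exp = np.array([expected[k] for k in range(1, 9)])
        assert np.corrcoef(meas, exp)[0, 1] > 0.9

    def test_empty_condition_raises(self, task_dataset):
        d = task_dataset["BC"]
        only17 = d["trials"][d["trials"].target_id == -1]
        with pytest.raises(ValueError, match="empty condition"):
            mp.condition_mask(("target", 99), 1000, d["trials"], fs=FS)


class TestFrequencyProfile:
    def test_profile_peaks_at_coupling_frequency(self, meso300, beta300):
        p = synth.TaskParams(r_baseline=20.0, amp_p2=-8.0, amp_p4=0.15,
                             w_b1=5.0)
        tr = synth.generate_spikes(p, None, beta300, seed=48)
        freqs = [10.0, 16.0, 22.0, 28.0, 36.0, 46.0]
        prof = mp.frequency_profile(meso300.s_L, tr, freqs)
        assert prof.loc[prof.amp_range.idxmax(), "freq"] == 28.0
        assert prof.loc[prof.phase_range.idxmax(), "freq"] == 28.0

    def test_uncoupled_unit_flat_profiles(self, meso300, beta300):
        tr = synth.generate_spikes(synth.TaskParams(r_baseline=20.0), None,
                                   beta300, seed=49)
        prof = mp.frequency_profile(meso300.s_L, tr, [16.0, 28.0, 46.0])
        assert np.all(prof.amp_range < 3.0)
        assert np.all(prof.phase_range < 3.0)


class TestExternalTuning:
    def test_untuned_unit_components_near_zero(self, task_dataset):
        d = task_dataset["BC"]
        tr = synth.generate_spikes(synth.TaskParams(r_baseline=20.0), None,
                                   d["sig"], seed=50)
        model = mp.external_tuning(tr, d["trials"])
        assert np.abs(model.r_trial).max() < 8.0
        assert max(abs(v) for v in model.r_target.values()) < 4.0

    def test_idempotent_on_refit(self, task_dataset):
        d = task_dataset["BC"]
        tr = synth.generate_spikes(synth.TaskParams(r_baseline=20.0), None,
                                   d["sig"], seed=51)
        m1 = mp.external_tuning(tr, d["trials"])
        m2 = mp.external_tuning(tr, d["trials"])
        assert m1.r_baseline == m2.r_baseline
        assert np.array_equal(m1.r_trial, m2.r_trial)
        assert m1.r_target == m2.r_target

    def test_heldout_prediction_slope_near_one(self, task_dataset):
        d = task_dataset["BC"]
        sig = d["sig"]
        p = synth.TaskParams(r_baseline=25.0, target_pref=2, target_depth=10.0,
                             r_trial={"move_to_center": 5.0,
                                      "move_to_target": -12.0, "reward": 8.0})
        n = len(sig.z)
        tr_train = synth.generate_spikes(p, None, sig, trials=d["trials"], seed=52)
        tr_test = synth.generate_spikes(p, None, sig, trials=d["trials"], seed=53)
        model = mp.external_tuning(tr_train, d["trials"])
        pred = model.predict(d["trials"], n)
        inside = mp.trial_sample_mask(d["trials"], n, FS)
        _, slope, r2 = mp.evaluate_rate_prediction(pred, tr_test, 10,
                                                   valid=inside)
        assert slope == pytest.approx(1.0, abs=0.25)

    def test_missing_labels(self):
        import pandas as pd
        with pytest.raises(ValueError, match="missing"):
            mp.external_tuning(np.zeros(1000, np.uint8), pd.DataFrame())


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(500, 4000),
       rate=st.floats(5.0, 80.0))
def test_binning_conservation_property(seed, n, rate):
    """Count-weighted mean of bin rates equals the truncated global rate."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    s = (rng.random(n) < rate / FS).astype(np.uint8)
    m = mp.equal_count_binning(x, s, 10)
    assert m.rates.mean() == pytest.approx(
        s[: m.n_truncated].mean() * FS, abs=1e-9)
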