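"""Validation metrics: smoothness, peaks, onset/offset table, Wilcoxon, C sweep."""

import itertools

import numpy as np
import pytest
from scipy import stats

from tasknorm import (
    NormalizationConfig,
    c_sweep,
    compare_versions,
    normalize_v1,
    normalize_v2,
    onset_offset_table,
    peak_preservation,
    smoothness_index,
    wilcoxon_signed_rank,
)
from tasknorm.normalization import NormalizedTrial

from conftest import make_trial, make_trialset


class TestSmoothnessIndex:
    def test_linear_ramp_is_perfectly_smooth(self):
        assert smoothness_index(np.linspace(0, 5, 50)) == pytest.approx(
            0.0, abs=1e-14
        )

    def test_alternating_sequence_hand_value(self):
        # diffs of [0,1,0,1] are [1,-1,1]; sample SD = 2/sqrt(3)
        assert smoothness_index(np.array([0.0, 1, 0, 1])) == pytest.approx(
            1.1547005, abs=1e-6
        )

    def test_translation_invariant_and_scales_linearly(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=200)
        s = smoothness_index(v)
        assert smoothness_index(v + 17.0) == pytest.approx(s, rel=1e-12)
        assert smoothness_index(3.0 * v) == pytest.approx(3.0 * s, rel=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            smoothness_index(np.array([1.0, 2.0]))


class TestPeakPreservation:
    def test_identity_limit_is_zero(self, config):
        trial = make_trial(7.0, config)
        ntrial = NormalizedTrial(
            percent=100 * trial.times / trial.times[-1],
            values=trial.values,
            onset_percent=100 * trial.onset_s / trial.times[-1],
            offset_percent=100 * trial.offset_s / trial.times[-1],
            times_s=trial.times,
        )
        err = peak_preservation(trial, ntrial)
        assert err.euclid < 1e-9
        assert err.dt_max < 1e-9 and err.da_min < 1e-9

    def test_parabola_peak_between_samples(self, config):
        """Raw samples of a parabola whose vertex falls between samples: the
        dense spline locates the vertex better than the raw argmax."""
        vertex = 5.03  # not a multiple of the 1/10.27 s sample period
        f = lambda t: -((t - vertex) ** 2)
        trial = make_trial(6.0, config, func=f)
        nts = normalize_v1(
            make_trialset([6.0, 6.0], config, func=f)
        )
        err = peak_preservation(trial, nts.trials[0])
        assert err.dt_max <= 1.0 / 10.27 + 1e-9
        raw_peak_t = trial.times[np.argmax(trial.values[:, 0, 0])]
        norm_peak_t = nts.trials[0].times_s[
            np.argmax(nts.trials[0].values[:, 0, 0])
        ]
        assert abs(norm_peak_t - vertex) <= abs(raw_peak_t - vertex) + 1e-12

    def test_all_nan_channel_skipped(self, config):
        ts = make_trialset([6.0, 6.0], config)
        for t in ts.trials:
            t.values = np.concatenate([t.values, np.full_like(t.values, np.nan)],
                                      axis=1)
        nts = normalize_v1(ts)
        err = peak_preservation(ts.trials[0], nts.trials[0])
        assert np.isfinite(err.euclid)


class TestOnsetOffsetTable:
    def test_v1_sd_rows_exactly_zero(self, config):
        ts = make_trialset([5.0, 6.6, 8.1, 7.4], config)
        table = onset_offset_table(normalize_v1(ts), normalize_v2(ts))
        sd = table[(table.version == 1) & (table.statistic == "sd")]
        assert (sd.onset_percent == 0.0).all()
        assert (sd.offset_percent == 0.0).all()

    def test_v2_mean_onset_arithmetic(self, config):
        ts = make_trialset([8.0, 9.0, 10.0], config)
        table = onset_offset_table(normalize_v1(ts), normalize_v2(ts))
        mean = table[(table.version == 2) & (table.statistic == "mean")]
        assert mean.onset_percent.iloc[0] == pytest.approx(14.3346, abs=1e-3)

    def test_equal_durations_versions_agree(self, config):
        ts = make_trialset([7.0, 7.0, 7.0], config)
        table = onset_offset_table(normalize_v1(ts), normalize_v2(ts))
        means = table[table.statistic == "mean"]
        v1_on, v2_on = means.onset_percent.to_numpy()
        # grids differ by at most one point, so onsets agree to grid rounding
        assert abs(v1_on - v2_on) < 100.0 / (7.0 + 5.0) / 50  # one grid step

    def test_version_mismatch_rejected(self, config):
        ts = make_trialset([6.0, 7.0], config)
        v1 = normalize_v1(ts)
        with pytest.raises(ValueError, match="version-1 and a version-2"):
            onset_offset_table(v1, v1)


class TestWilcoxon:
    def test_all_positive_small_sample(self):
        w, p = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))
        assert w == 0.0
        assert p == pytest.approx(0.25)

    def test_symmetric_pairs_give_p_one(self):
        w, p = wilcoxon_signed_rank(np.array([1.0, -1.0, 2.0, -2.0]))
        assert p == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.zeros(5))

    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_exact_p_equals_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(0.4, 1.0, size=n)
        d[d == 0] = 0.1
        w, p = wilcoxon_signed_rank(d)
        ranks = stats.rankdata(np.abs(d))
        w_plus_obs = ranks[d > 0].sum()
        total = ranks.sum()
        lo = min(w_plus_obs, total - w_plus_obs)
        hi = max(w_plus_obs, total - w_plus_obs)
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            wp = sum(r for r, s in zip(ranks, signs) if s)
            if wp <= lo + 1e-12 or wp >= hi - 1e-12:
                count += 1
        assert p == pytest.approx(count / 2**n, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.3, 1.0, size=15)
        w, p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, method="exact")
        assert w == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_close_to_normal_approximation_at_n24(self):
        rng = np.random.default_rng(24)
        d = rng.normal(0.2, 1.0, size=24)
        _, p_exact = wilcoxon_signed_rank(d)
        # push the same data through the large-sample branch
        big = np.concatenate([d, np.zeros(0)])
        import tasknorm.metrics as m

        old = m.EXACT_WILCOXON_MAX_N
        try:
            m.EXACT_WILCOXON_MAX_N = 0
            _, p_approx = wilcoxon_signed_rank(big)
        finally:
            m.EXACT_WILCOXON_MAX_N = old
        assert abs(p_exact - p_approx) < 0.02


class TestVersionComparisonAndSweep:
    def test_compare_versions_shapes_and_p_range(self, config):
        rng = np.random.default_rng(2)
        f = lambda t: np.sin(2 * np.pi * 0.12 * t) + 0.05 * rng.standard_normal(
            t.size
        )
        ts = make_trialset([5.5, 6.6, 7.7, 8.2, 6.1, 7.0], config, func=f)
        comp = compare_versions(normalize_v1(ts), normalize_v2(ts))
        assert comp.smooth_v1.shape == comp.smooth_v2.shape == (6,)
        assert 0 < comp.p_two_sided <= 1
        assert comp.w_stat >= 0
        assert np.all(comp.onset_err >= 0)

    def test_constant_signal_zero_error_for_all_c(self, config):
        ts = make_trialset([6.0, 8.0], config, func=lambda t: 2.0 + 0 * t)
        sweep = c_sweep(ts, [10, 20, 40])
        assert max(sweep.errors) < 1e-10
        assert sweep.stable_c == 10

    def test_error_shrinks_with_denser_grid(self, config):
        """Band-limited signal: the peak error at C=100 is no worse than C=10."""
        f = lambda t: np.sin(2 * np.pi * 0.15 * t) + 0.4 * np.cos(
            2 * np.pi * 0.07 * t
        )
        ts = make_trialset([6.3, 7.9, 5.8], config, func=f)
        sweep = c_sweep(ts, [10, 100])
        assert sweep.errors[1] <= sweep.errors[0] + 1e-12

    def test_unsorted_c_values_rejected(self, config):
        ts = make_trialset([6.0, 8.0], config)
        with pytest.raises(ValueError, match="sorted"):
            c_sweep(ts, [50, 10])
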