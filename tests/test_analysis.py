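"""RT statistics, Wilcoxon signed-rank and reciprobit regression."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from saccade_race import analysis, fixtures
from saccade_race.analysis import (
    CumulativeDistribution,
    coefficient_of_variation,
    compare_lines,
    cumulative_distribution,
    fitted_median_ms,
    reciprobit_fit,
    reciprobit_points,
    summarize,
    wilcoxon_signed_rank,
)
from saccade_race.exceptions import DegenerateDataError, InvalidInputError
from saccade_race.trial import TrialResult


def _trial(outcome, rt_error=None, rt_anti=None, rt_corrected=None):
    return TrialResult(
        outcome=outcome,
        t_cross_error_ms=None if rt_error is None else rt_error + 20,
        t_cross_correct_ms=None,
        rt_error_ms=rt_error,
        rt_anti_ms=rt_anti,
        rt_corrected_ms=rt_corrected,
        tau_left=0.017,
        tau_right=0.0065,
        seed=0,
    )


class TestCV:
    def test_hand_computed_quartiles(self):
        # Q25=150, Q75=250, median=200 under linear-interpolation quantiles
        assert coefficient_of_variation([100, 150, 200, 250, 300]) == pytest.approx(0.5)

    def test_constant_sample_has_zero_cv(self):
        assert coefficient_of_variation(fixtures.make_fixture("degenerate")) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            coefficient_of_variation([])

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, k):
        rts = np.array([120.0, 180.0, 210.0, 260.0, 400.0])
        assert coefficient_of_variation(k * rts) == pytest.approx(
            coefficient_of_variation(rts), rel=1e-9
        )

    def test_matches_numpy_type7_quantiles(self, rng):
        rts = rng.gamma(5.0, 40.0, size=137)
        q25, med, q75 = np.quantile(rts, [0.25, 0.5, 0.75])
        assert coefficient_of_variation(rts) == pytest.approx((q75 - q25) / med)


class TestSummarize:
    def test_counting_example(self):
        # 10 trials, 4 with error crossings, all corrected
        trials = [_trial("corrected_antisaccade", rt_error=200.0, rt_corrected=150.0)
                  for _ in range(4)]
        trials += [_trial("antisaccade", rt_anti=300.0) for _ in range(6)]
        s = summarize(trials)
        assert s.error_rate_percent == pytest.approx(40.0)
        assert s.percent_errors_corrected == pytest.approx(100.0)
        assert s.n_valid_trials == 10

    def test_no_response_excluded_from_rates(self):
        trials = [_trial("no_response")] * 5
        trials += [_trial("error_prosaccade_uncorrected", rt_error=250.0)] * 5
        s = summarize(trials)
        assert s.n_valid_trials == 5
        assert s.error_rate_percent == pytest.approx(100.0)
        assert s.percent_errors_corrected == pytest.approx(0.0)

    def test_absent_category_is_none_not_zero(self):
        s = summarize([_trial("antisaccade", rt_anti=310.0)] * 3)
        assert s.error_prosaccade is None
        assert s.corrected_antisaccade is None
        assert s.antisaccade.median_ms == pytest.approx(310.0)
        assert s.error_rate_percent == pytest.approx(0.0)
        assert s.percent_errors_corrected is None

    def test_trial_order_invariance(self, tiny_control_ensemble, rng):
        trials = list(tiny_control_ensemble.trials)
        shuffled = list(trials)
        rng.shuffle(shuffled)
        assert summarize(trials) == summarize(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize([])


class TestCumulativeDistribution:
    def test_grid_and_endpoints(self):
        d = cumulative_distribution(np.arange(1.0, 21.0))
        assert list(d.percentiles) == list(range(5, 101, 5))
        # linear-interpolation (type 7) quantiles on 1..20
        assert d.rt_at_percentile[0] == pytest.approx(1.95)
        assert d.rt_at_percentile[-1] == pytest.approx(20.0)
        assert d.rt_at_percentile[9] == pytest.approx(10.5)  # the median

    def test_constant_input_is_flat(self):
        d = cumulative_distribution(np.full(50, 250.0))
        assert np.all(d.rt_at_percentile == 250.0)

    @given(st.lists(st.floats(1.0, 1e4), min_size=1, max_size=60))
    @settings(max_examples=40, deadline=None)
    def test_output_monotone(self, rts):
        d = cumulative_distribution(rts)
        assert np.all(np.diff(d.rt_at_percentile) >= 0)

    def test_adding_constant_shifts_quantiles(self, rng):
        rts = rng.gamma(4.0, 50.0, size=80)
        base = cumulative_distribution(rts).rt_at_percentile
        shifted = cumulative_distribution(rts + 25.0).rt_at_percentile
        assert shifted == pytest.approx(base + 25.0)


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        a = np.arange(10.0)
        with pytest.raises(DegenerateDataError):
            wilcoxon_signed_rank(a, a)

    def test_all_positive_n6_exact(self):
        # maximal statistic; exact two-sided p = 2/2^6
        a = np.array([10.0, 12, 14, 16, 18, 20])
        b = a - 1.0
        res = wilcoxon_signed_rank(a, b)
        assert res.statistic == pytest.approx(21.0)
        assert res.p == pytest.approx(2 / 64)
        assert res.z > 0

    def test_exact_p_matches_enumeration(self, rng):
        # independent oracle: enumerate all sign assignments directly
        a = rng.normal(0, 1, size=9)
        b = rng.normal(0, 1, size=9)
        d = a - b
        ranks = sstats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        stats = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=9)
        ]
        lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
        p_exact = sum(1 for w in stats if w <= lo or w >= hi) / len(stats)
        assert wilcoxon_signed_rank(a, b).p == pytest.approx(p_exact)

    def test_sign_flip_negates_z(self, rng):
        a = rng.normal(300, 30, size=25)
        b = a + rng.normal(5, 10, size=25)
        r1 = wilcoxon_signed_rank(a, b)
        r2 = wilcoxon_signed_rank(b, a)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_scipy_approx(self, rng):
        # cross-check the normal approximation against scipy's implementation
        a = rng.normal(300, 30, size=40)
        b = a + rng.normal(8, 20, size=40)
        mine = wilcoxon_signed_rank(a, b)
        ref = sstats.wilcoxon(a, b, correction=True, method="approx")
        assert abs(mine.z) == pytest.approx(abs(ref.zstatistic), rel=1e-9)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            wilcoxon_signed_rank([1.0, 2.0], [2.0, 1.0])


class TestReciprobit:
    def test_median_percentile_maps_to_zero_probit(self):
        d = cumulative_distribution(np.linspace(200, 400, 100))
        x, y = reciprobit_points(d)
        assert y[9] == pytest.approx(0.0)  # the 50% grid point
        assert x.size == 19  # 100% excluded

    def test_recinormal_sample_fits_a_line(self):
        fx = fixtures.make_fixture("recinormal-rts", seed=1, n=10_000)
        fit = reciprobit_fit(cumulative_distribution(fx.rts))
        assert fit.r > 0.99
        assert fitted_median_ms(fit) == pytest.approx(fx.median_ms, rel=0.02)

    def test_slope_and_intercept_recover_rate_parameters(self):
        # for 1/RT ~ Normal(m, s): probit(p) = (1/s)*(-(-1/RT)) ... the line
        # has slope 1/s and intercept -m/s
        fx = fixtures.make_fixture("recinormal-rts", seed=2, n=10_000)
        fit = reciprobit_fit(cumulative_distribution(fx.rts))
        assert fit.slope == pytest.approx(1.0 / fx.rate_sd, rel=0.05)
        assert -fit.intercept / fit.slope == pytest.approx(-fx.rate_mean, rel=0.05)

    def test_too_few_points_rejected(self):
        d = CumulativeDistribution(np.array([50, 100]), np.array([200.0, 300.0]))
        with pytest.raises(InvalidInputError):
            reciprobit_fit(d)


class TestCompareLines:
    @staticmethod
    def _line_points(slope, intercept, n=20, noise_sd=0.0, seed=0, span=(0.0, 1.0)):
        rng = np.random.default_rng(seed)
        x = np.linspace(*span, n)
        y = intercept + slope * x + rng.normal(0, noise_sd, size=n)
        return x, y

    def test_identical_sets_give_zero_statistics(self):
        # exact-fit degenerate case: both t statistics vanish (up to float
        # noise amplified by the zero residual variance)
        pts = self._line_points(500.0, 2.0, span=(-0.006, -0.002))
        res = compare_lines(pts, pts)
        assert abs(res.t_slope) < 0.1
        assert abs(res.t_intercept) < 0.1

    def test_vertical_shift_hits_intercept_only(self):
        a = self._line_points(500.0, 2.0, span=(-0.006, -0.002))
        b = (a[0], a[1] + 0.5)
        res = compare_lines(a, b)
        assert abs(res.t_slope) < 0.1
        assert abs(res.t_intercept) > 10

    def test_different_slopes_detected(self):
        # noisy sets from slopes 1 vs 2; the interaction term must reject
        a = self._line_points(1.0, 0.0, noise_sd=0.01, seed=1)
        b = self._line_points(2.0, 0.0, noise_sd=0.01, seed=2)
        res = compare_lines(a, b)
        assert res.df_slope == 36
        assert res.p_slope < 0.01

    def test_statsmodels_free_oracle(self):
        # independent check of the slope t statistic: direct two-regression
        # formula with pooled residual variance
        a = self._line_points(1.0, 0.0, noise_sd=0.05, seed=3)
        b = self._line_points(1.4, 0.0, noise_sd=0.05, seed=4)
        res = compare_lines(a, b)

        def fit(x, y):
            sl, ic = np.polyfit(x, y, 1)
            resid = y - (ic + sl * x)
            sxx = ((x - x.mean()) ** 2).sum()
            return sl, resid, sxx

        sl_a, res_a, sxx_a = fit(*a)
        sl_b, res_b, sxx_b = fit(*b)
        df = len(a[0]) + len(b[0]) - 4
        s2 = (np.sum(res_a**2) + np.sum(res_b**2)) / df
        t_manual = (sl_b - sl_a) / np.sqrt(s2 * (1 / sxx_a + 1 / sxx_b))
        assert res.t_slope == pytest.approx(t_manual, rel=1e-6)

    def test_degenerate_predictor_rejected(self):
        x = np.full(5, -0.004)
        y = np.arange(5.0)
        with pytest.raises(InvalidInputError):
            compare_lines((x, y), (x, y))
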