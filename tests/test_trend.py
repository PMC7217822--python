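"""Regression fits against closed-form/statsmodels oracles; binomial PLR."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

import vfprog as v
from vfprog import trend as tr


def make_series(td_matrix, times, eye_id="e"):
    return v.VFSeries(
        eye_id,
        [v.VisualField(td, t=float(t)) for td, t in zip(td_matrix, times)],
    )


class TestOlsFit:
    def test_collinear_points_exact(self):
        fit = v.ols_fit([0.0, 1.0, 2.0], [0.0, -1.0, -2.0])
        assert fit.slope == pytest.approx(-1.0, abs=1e-14)
        assert fit.intercept == pytest.approx(0.0, abs=1e-14)

    def test_constant_y_zero_slope(self):
        fit = v.ols_fit([0.0, 1.0, 2.0, 3.0], [4.0] * 4)
        assert fit.slope == pytest.approx(0.0, abs=1e-14)
        assert fit.slope_p == 1.0

    def test_matches_statsmodels(self, rng):
        t = np.sort(rng.uniform(0, 5, 8))
        y = -0.5 * t + rng.normal(0, 1, 8)
        fit = v.ols_fit(t, y)
        ref = sm.OLS(y, sm.add_constant(t)).fit()
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-10)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-10)
        assert fit.slope_p == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            v.ols_fit([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_two_points_have_no_p_value(self):
        fit = v.ols_fit([0.0, 1.0], [0.0, -1.0])
        assert fit.n == 2 and np.isnan(fit.slope_p)


class TestWeightedFit:
    def test_equal_weights_reproduce_ols(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            t = np.sort(rng.uniform(0, 6, n))
            t[1:] += 1e-3  # ensure distinct
            y = rng.normal(0, 2, n)
            c = float(rng.uniform(0.1, 10))
            f1 = v.ols_fit(t, y)
            f2 = v.weighted_fit(t, y, np.full(n, c))
            assert f2.slope == pytest.approx(f1.slope, abs=1e-10)
            assert f2.intercept == pytest.approx(f1.intercept, abs=1e-10)
            assert f2.slope_p == pytest.approx(f1.slope_p, abs=1e-10)

    def test_dominant_weight_pins_line_to_point(self, rng):
        t = np.arange(8.0)
        y = rng.normal(-5, 2, 8)
        w = np.ones(8)
        w[3] = 1e6
        fit = v.weighted_fit(t, y, w)
        assert abs(fit.predict(t[3]) - y[3]) < 1e-3

    def test_matches_statsmodels_wls(self, rng):
        for _ in range(50):
            t = np.sort(rng.uniform(0, 6, 8))
            y = rng.normal(-5, 2, 8)
            w = rng.uniform(0.1, 5, 8)
            fit = v.weighted_fit(t, y, w)
            ref = sm.WLS(y, sm.add_constant(t), weights=w).fit()
            assert fit.slope == pytest.approx(ref.params[1], abs=1e-10)
            assert fit.intercept == pytest.approx(ref.params[0], abs=1e-10)
            assert fit.slope_p == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_all_weight_on_one_time_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            v.weighted_fit([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], [0.0, 5.0, 0.0])


class TestVaeWeights:
    def _pair(self, rng, n=5):
        times = np.arange(n) * 0.5
        series = make_series(rng.uniform(-30, 0, (n, 52)), times)
        recon = make_series(series.td_matrix.copy(), times)
        return series, recon

    def test_perfect_reconstruction_capped_by_epsilon(self, rng):
        series, recon = self._pair(rng)
        w = v.vae_weights(series, recon, v.WeightScheme("vae_mtd", epsilon=0.01))
        np.testing.assert_allclose(w, 100.0)

    def test_two_db_difference_gives_half_weight(self, rng):
        series, recon = self._pair(rng)
        recon.exams[2] = v.VisualField(recon.exams[2].td + 2.0, t=recon.exams[2].t)
        w = v.vae_weights(series, recon, v.WeightScheme("vae_mtd"))
        assert w[2] == pytest.approx(0.5)

    def test_doubling_errors_halves_weights(self, rng):
        series, recon = self._pair(rng)
        delta = rng.uniform(0.5, 3.0, (5, 52))
        r1 = make_series(series.td_matrix + delta, series.times)
        r2 = make_series(series.td_matrix + 2 * delta, series.times)
        scheme = v.WeightScheme("vae_pointwise", epsilon=1e-9)
        np.testing.assert_allclose(
            v.vae_weights(series, r1, scheme), 2 * v.vae_weights(series, r2, scheme)
        )

    def test_unweighted_mode_is_all_ones(self, rng):
        series, _ = self._pair(rng)
        np.testing.assert_array_equal(
            v.vae_weights(series, None, v.WeightScheme("unweighted")), np.ones(5)
        )

    def test_misaligned_series_rejected(self, rng):
        series, recon = self._pair(rng)
        short = v.VFSeries(recon.eye_id, recon.exams[:-1])
        with pytest.raises(ValueError, match="misaligned"):
            v.vae_weights(series, short, v.WeightScheme("vae_mtd"))


class TestMtdTrend:
    def test_unweighted_reproduces_ols_on_mtd(self, rng):
        series = make_series(rng.uniform(-30, 0, (6, 52)), np.arange(6) * 0.6)
        fit = v.mtd_trend(series)
        ref = v.ols_fit(series.times, series.mtd)
        assert fit.slope == pytest.approx(ref.slope, abs=1e-12)

    def test_minimal_length_series(self, rng):
        series = make_series(rng.uniform(-30, 0, (3, 52)), [0.0, 0.5, 1.0])
        fit = v.mtd_trend(series)
        assert fit.n == 3 and 0 <= fit.slope_p <= 1

    def test_noise_free_prediction_exact(self):
        td = np.stack([np.full(52, -5.0 - 0.8 * t) for t in np.arange(6) * 0.5])
        series = make_series(td, np.arange(6) * 0.5)
        for k in range(2, 6):
            pred = v.predict_future_mtd(series.truncate(k), t_target=2.5)
            assert pred == pytest.approx(-5.0 - 0.8 * 2.5, abs=1e-9)

    def test_significance_rule_requires_negative_slope(self):
        improving = v.RegressionFit(0.5, -5.0, 0.001, 10, np.ones(10))
        worsening = v.RegressionFit(-0.5, -5.0, 0.001, 10, np.ones(10))
        flat = v.RegressionFit(-0.5, -5.0, 0.2, 10, np.ones(10))
        assert not v.trend_is_significant(improving)
        assert v.trend_is_significant(worsening)
        assert not v.trend_is_significant(flat)


class TestPointwisePLR:
    def test_constant_points_give_half(self):
        td = np.tile(np.linspace(-20, 0, 52), (6, 1))
        series = make_series(td, np.arange(6) * 0.5)
        _, p = v.pointwise_plr(series)
        np.testing.assert_allclose(p, 0.5)

    def test_deterministic_decline_gives_tiny_p(self):
        times = np.arange(8) * 0.5
        td = np.tile(np.full(52, -5.0), (8, 1))
        td[:, 7] = -5.0 - 2.0 * times
        series = make_series(td, times)
        _, p = v.pointwise_plr(series)
        assert p[7] < 1e-6
        assert np.all(p[np.arange(52) != 7] == 0.5)

    def test_matches_scipy_linregress_oracle(self, rng):
        times = np.sort(rng.uniform(0, 5, 9))
        td = rng.normal(-10, 3, (9, 52))
        series = make_series(td, times)
        _, p = v.pointwise_plr(series)
        for j in range(0, 52, 7):
            res = stats.linregress(times, td[:, j])
            tstat = res.slope / res.stderr
            expected = stats.t.cdf(tstat, 7)
            assert p[j] == pytest.approx(expected, abs=1e-10)

    def test_weighted_matches_statsmodels_per_point(self, rng):
        times = np.sort(rng.uniform(0, 5, 8))
        td = rng.normal(-10, 3, (8, 52))
        series = make_series(td, times)
        recon = make_series(td + rng.uniform(0.2, 3.0, (8, 52)), times)
        scheme = v.WeightScheme("vae_pointwise")
        w = v.vae_weights(series, recon, scheme)
        fits, p = v.pointwise_plr(series, scheme, recon)
        for j in (0, 25, 51):
            ref = sm.WLS(td[:, j], sm.add_constant(times), weights=w[:, j]).fit()
            assert fits[j].slope == pytest.approx(ref.params[1], abs=1e-10)
            tstat = ref.params[1] / ref.bse[1]
            assert p[j] == pytest.approx(stats.t.cdf(tstat, 6), abs=1e-10)

    def test_too_short_series_rejected(self, rng):
        series = make_series(rng.uniform(-30, 0, (2, 52)), [0.0, 0.5])
        with pytest.raises(ValueError, match="3 exams"):
            v.pointwise_plr(series)


def binom_tail_oracle(k, n, c):
    return sum(math.comb(n, i) * c**i * (1 - c) ** (n - i) for i in range(k, n + 1))


class TestBinomialPLR:
    def test_all_null_pvalues(self):
        res = v.binomial_plr(np.full(52, 0.5))
        assert all(k == 0 for k in res.counts_below.values())
        assert all(p == 1.0 for p in res.binom_p.values())
        assert not res.significant

    def test_tail_matches_exact_enumeration(self):
        p = np.full(52, 0.5)
        p[:6] = 0.04  # 6 points under 0.05 and 0.075 and 0.1, none under 0.025
        res = v.binomial_plr(p)
        assert res.counts_below[0.05] == 6
        assert res.binom_p[0.05] == pytest.approx(binom_tail_oracle(6, 52, 0.05), abs=1e-12)
        for c in v.BINOMIAL_CUTOFFS:
            k = res.counts_below[c]
            assert res.binom_p[c] == pytest.approx(binom_tail_oracle(k, 52, c), abs=1e-12)

    def test_median_is_mean_of_middle_two(self, rng):
        p = rng.uniform(0, 1, 52)
        res = v.binomial_plr(p)
        ordered = np.sort(list(res.binom_p.values()))
        assert res.median_p == pytest.approx(0.5 * (ordered[1] + ordered[2]))

    def test_strict_inequality_at_cutoff(self):
        p = np.full(52, 0.5)
        p[0] = 0.05  # exactly at the cutoff: not counted
        assert v.binomial_plr(p).counts_below[0.05] == 0

    def test_lowering_a_pvalue_never_raises_median(self, rng):
        for _ in range(50):
            p = rng.uniform(0, 1, 52)
            res = v.binomial_plr(p)
            q = p.copy()
            j = int(rng.integers(0, 52))
            q[j] = q[j] * rng.uniform(0, 1)
            assert v.binomial_plr(q).median_p <= res.median_p + 1e-12

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            v.binomial_plr(np.full(54, 0.5))

    def test_series_wrapper_composes(self, rng):
        times = np.arange(6) * 0.5
        series = make_series(rng.normal(-10, 3, (6, 52)), times)
        _, p = v.pointwise_plr(series)
        direct = v.binomial_plr(p)
        wrapped = v.binomial_plr_series(series)
        assert wrapped.median_p == direct.median_p
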