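"""Quota decision regressions: likelihood, fitting, threshold summaries."""

import numpy as np
import pytest
from scipy import stats

import lynxcast as lx
from lynxcast.quota import QuotaPosterior, QuotaSeries, quota_log_likelihood


def _settings(seed=0):
    return lx.FitSettings(n_chains=2, n_iter=6000, n_burnin=2000, thin=4, seed=seed)


class TestQuotaSeries:
    def test_rejects_negative_and_mismatched(self):
        with pytest.raises(ValueError):
            QuotaSeries(x=[1, 2], q=[3])
        with pytest.raises(ValueError):
            QuotaSeries(x=[1, -2, 3], q=[1, 2, 3])


class TestQuotaLikelihood:
    def test_degenerate_sigma_reduces_to_poisson(self):
        series = QuotaSeries(x=[40], q=[35])
        got = quota_log_likelihood(-10.0, 1.2, 1e-12, series)
        assert got == pytest.approx(stats.poisson.logpmf(35, -10 + 1.2 * 40))

    def test_quadrature_matches_monte_carlo(self, rng):
        series = QuotaSeries(x=[30, 50], q=[20, 60])
        b0, b1, sq = -20.0, 1.5, 0.3
        got = quota_log_likelihood(b0, b1, sq, series)
        # independent oracle: brute-force Monte Carlo integration
        total = 0.0
        for x, q in zip(series.x, series.q):
            H = np.exp(rng.normal(np.log(max(b0 + b1 * x, 1e-6)), sq, 400_000))
            total += np.log(np.mean(stats.poisson.pmf(q, H)))
        assert got == pytest.approx(total, abs=0.01)

    def test_invariant_to_pair_order(self):
        a = QuotaSeries(x=[10, 40, 70], q=[0, 25, 80])
        b = QuotaSeries(x=[70, 10, 40], q=[80, 0, 25])
        assert quota_log_likelihood(-20, 1.4, 0.25, a) == pytest.approx(
            quota_log_likelihood(-20, 1.4, 0.25, b)
        )

    def test_flat_regression_decreasing_in_quota(self):
        vals = [
            quota_log_likelihood(1e-6, 0.0, 0.2, QuotaSeries(x=[50], q=[q]))
            for q in (1, 3, 8)
        ]
        assert vals[0] > vals[1] > vals[2]


class TestFitQuotaModel:
    def test_proportional_slope_recovery(self):
        x = np.arange(20, 90, 5)
        series = QuotaSeries(x=x, q=np.round(2.0 * x).astype(int))
        post = lx.fit_quota_model(series, model="proportional",
                                  settings=_settings())
        b1 = post.b1.reshape(-1)
        assert np.median(b1) == pytest.approx(2.0, abs=0.1)
        assert post.b0 is None

    def test_threshold_recovery(self, rng):
        # generate exactly from the threshold regression with -b0/b1 = 52,
        # interior to the gap between the censuses bracketing the threshold
        rule = lx.ThresholdRule(b0=-62.4, b1=1.2, sigma_q=0.1)
        x = np.concatenate([np.arange(30, 105, 5)] * 2)
        series = lx.simulate_quota_series(rule, np.append(x, 0), seed=8)
        post = lx.fit_quota_model(series, model="threshold",
                                  settings=_settings(seed=2))
        thr = post.threshold_draws
        lo, hi = np.percentile(thr, [2.5, 97.5])
        assert lo <= 52 <= hi
        summary = lx.threshold_summary(post)
        assert summary["p_leq_0"] < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            lx.fit_quota_model(QuotaSeries(x=[1, 2], q=[1, 2]))

    def test_model1_slope_invariant_to_origin_pair(self):
        x = np.arange(20, 80, 5)
        base = QuotaSeries(x=x, q=np.round(1.5 * x).astype(int))
        with_origin = QuotaSeries(
            x=np.concatenate(([0], x)),
            q=np.concatenate(([0], np.round(1.5 * x).astype(int))),
        )
        p1 = lx.fit_quota_model(base, "proportional", settings=_settings(seed=4))
        p2 = lx.fit_quota_model(
            with_origin, "proportional", settings=_settings(seed=4)
        )
        assert np.median(p1.b1) == pytest.approx(np.median(p2.b1), abs=0.05)


class TestThresholdSummary:
    def _const_posterior(self, b0, b1):
        shape = (1, 200)
        return QuotaPosterior(
            model="threshold",
            b0=np.full(shape, b0),
            b1=np.full(shape, b1),
            sigma_q=np.full(shape, 0.2),
        )

    def test_published_coefficient_ratio(self):
        # ratio of the Swedish posterior means
        summary = lx.threshold_summary(self._const_posterior(-75.1, 1.09))
        assert summary["mean"] == pytest.approx(68.9, abs=0.05)
        assert summary["p_leq_0"] == 0.0

    def test_zero_intercept_gives_zero_threshold(self):
        summary = lx.threshold_summary(self._const_posterior(0.0, 1.5))
        assert summary["mean"] == 0.0 and summary["p_leq_0"] == 1.0

    def test_model1_posterior_rejected(self):
        post = QuotaPosterior(
            model="proportional",
            b1=np.ones((1, 10)),
            sigma_q=np.full((1, 10), 0.2),
        )
        with pytest.raises(ValueError):
            lx.threshold_summary(post)

    def test_regression_line_crosses_zero_at_threshold(self):
        post = self._const_posterior(-60.0, 2.0)
        thr = post.threshold_draws
        assert np.allclose(-60.0 + 2.0 * thr, 0.0)

    def test_slope_comparison_direction(self):
        from lynxcast.quota import compare_slopes

        steep = self._const_posterior(-60.0, 2.5)
        shallow = self._const_posterior(-10.0, 1.0)
        assert compare_slopes(steep, shallow) == 1.0
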