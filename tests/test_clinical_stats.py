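"""Transforms, outlier rule, correlations and hierarchical regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from flairmap import clinical_stats as cs


class TestDetectOutliers:
    def test_exactly_three_sd_is_flagged(self):
        # 17 zeros plus +/- a: mean 0, sd(ddof=1) = a/3, so both extremes sit
        # at exactly 3.0 sample standard deviations
        x = np.concatenate([np.zeros(17), [-6.0, 6.0]])
        idx = cs.detect_outliers(x, k=3.0)
        assert set(idx) == {17, 18}

    def test_high_sdmt_style_outlier(self, rng):
        x = rng.normal(46.06, 12.16, size=51)
        x = np.append(x, x.mean() + 3.8 * x.std(ddof=1))
        assert 51 in cs.detect_outliers(x, k=3.0)

    def test_all_equal_no_outliers(self):
        assert cs.detect_outliers(np.full(10, 2.0)).size == 0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_direct_rule(self, seed):
        x = np.random.default_rng(seed).normal(size=40)
        idx = cs.detect_outliers(x, k=2.0)
        manual = np.flatnonzero(np.abs(x - x.mean()) >= 2.0 * x.std(ddof=1))
        np.testing.assert_array_equal(idx, manual)


class TestSelectTransform:
    def test_normal_sample_keeps_identity(self, rng):
        x = rng.normal(50, 5, size=200)
        _, label = cs.select_transform(x)
        assert label == "identity"

    def test_lognormal_sample_gets_log10(self, rng):
        x = 10 ** rng.normal(0, 0.5, size=200)
        tx, label = cs.select_transform(x)
        assert label == "log10"
        np.testing.assert_allclose(tx, np.log10(x))

    def test_zero_excludes_log_and_inverse(self, rng):
        x = np.abs(rng.normal(size=100)) ** 4
        x[0] = 0.0
        _, label = cs.select_transform(x)
        assert label in ("identity", "sqrt")


class TestLog10Transform:
    def test_values(self):
        np.testing.assert_allclose(cs.apply_transform_log10([100.0, 1.0]), [2.0, 0.0])
        np.testing.assert_allclose(
            cs.apply_transform_log10([0.01, 4.01]), [-2.0, 0.6031], atol=5e-5
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cs.apply_transform_log10([1.0, 0.0])


class TestPearson:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=30)
        r, p, n = cs.pearson(x, x)
        assert r == pytest.approx(1.0)

    def test_printed_pvalue_of_r_0344(self):
        assert round(cs.two_tailed_p_from_r(0.344, 51 - 2), 3) == 0.013

    def test_matches_covariance_oracle_and_scipy(self, rng):
        x, y = rng.normal(size=60), rng.normal(size=60)
        r, p, n = cs.pearson(x, y)
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(oracle, abs=1e-12)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cs.pearson(np.ones(10), np.arange(10.0))


class TestPartialCorr:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        r0, p0, n = cs.pearson(x, y)
        r1, p1, df = cs.partial_corr(x, y)
        assert (r1, p1) == (r0, p0)
        assert df == n - 2

    def test_df_for_one_covariate_at_n52(self, rng):
        x, y, c = rng.normal(size=(3, 52))
        _, _, df = cs.partial_corr(x, y, [c])
        assert df == 49

    def test_printed_pvalue_of_partial_r(self):
        assert round(cs.two_tailed_p_from_r(-0.433, 49), 3) == 0.002

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        x, y, c1, c2 = rng.normal(size=(4, 60))
        y = y + 0.5 * x + 0.3 * c1
        r, p, df = cs.partial_corr(x, y, [c1, c2])
        df_pg = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "c1": c1, "c2": c2}),
            x="x", y="y", covar=["c1", "c2"],
        )
        assert r == pytest.approx(float(df_pg["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(df_pg["p_val"].iloc[0]), abs=1e-8)

    def test_collinear_covariates_rejected(self, rng):
        x, y, c = rng.normal(size=(3, 30))
        with pytest.raises(ValueError, match="collinear"):
            cs.partial_corr(x, y, [c, 2 * c])


class TestHMR:
    def _data(self, rng, n=52):
        age = rng.normal(50, 8, n)
        wmv = rng.normal(720, 50, n) - 0.8 * (age - 50)
        t2lv = rng.normal(0, 0.5, n) + 0.01 * (age - 50)
        y = 1100 - 8 * (age - 50) + 2.2 * (wmv - 720) - 250 * t2lv + rng.normal(0, 250, n)
        return y, age, wmv, t2lv

    def test_single_predictor_r2_equals_pearson_squared(self, rng):
        y, age, *_ = self._data(rng)
        res = cs.hmr(y, [age[:, None]])
        r, _, _ = cs.pearson(age, y)
        assert res.stages[0].r2 == pytest.approx(r**2, abs=1e-12)
        # stage-1 F_change equals the overall model F
        t = r * np.sqrt(50 / (1 - r**2))
        assert res.stages[0].f_change == pytest.approx(t**2, rel=1e-10)

    def test_printed_adjusted_r2(self):
        assert round(cs.adjusted_r2(0.322, 52, 3), 3) == 0.280

    def test_r2_nondecreasing_and_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        y, age, wmv, t2lv = self._data(rng)
        res = cs.hmr(y, [age[:, None], wmv[:, None], t2lv[:, None]])
        r2s = res.r2_sequence
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))
        x_all = np.column_stack([age, wmv, t2lv])
        ref = sm.OLS(y, sm.add_constant(x_all)).fit()
        assert res.final_r2 == pytest.approx(ref.rsquared, abs=1e-10)
        assert res.stages[-1].adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-10)
        assert res.final_p == pytest.approx(ref.f_pvalue, abs=1e-12)

    def test_orthogonal_block_adds_nothing(self, rng):
        y, age, *_ = self._data(rng)
        n = y.size
        raw = rng.normal(size=n)
        z = np.column_stack([np.ones(n), age, y])
        ortho = raw - z @ np.linalg.lstsq(z, raw, rcond=None)[0]
        res = cs.hmr(y, [age[:, None], ortho[:, None]])
        assert res.stages[1].r2_change == pytest.approx(0.0, abs=1e-12)

    def test_standardized_betas_scale_invariant(self, rng):
        y, age, wmv, t2lv = self._data(rng)
        res1 = cs.hmr(y, [np.column_stack([age, wmv, t2lv])])
        res2 = cs.hmr(y, [np.column_stack([age * 1000 - 7, wmv, t2lv])])
        np.testing.assert_allclose(
            res1.final_betas["beta"], res2.final_betas["beta"], atol=1e-10
        )

    def test_rank_deficiency_names_stage(self, rng):
        y, age, *_ = self._data(rng)
        with pytest.raises(ValueError, match="stage 2"):
            cs.hmr(y, [age[:, None], (2 * age)[:, None]])


class TestSyntheticCohort:
    def test_deterministic_and_scaled(self):
        a = cs.synthetic_cohort(52, seed=4)
        b = cs.synthetic_cohort(52, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert a.t2lv_pct.min() > 0
        assert a.edss.between(0, 10).all()

    def test_planted_correlations_recovered(self):
        # average over replicates so the check tests the generator's target,
        # not one draw's sampling noise
        rs = []
        for seed in range(10):
            df = cs.synthetic_cohort(200, seed=seed)
            r, _, _ = cs.pearson(np.log10(df.t2lv_pct), df.sixmw_ft)
            rs.append(r)
        assert np.mean(rs) == pytest.approx(-0.513, abs=0.06)
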