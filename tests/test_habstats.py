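import numpy as np
import pandas as pd
import pytest

from salamet.errors import ValidationError
from salamet.habstats import (ci_from_summary, describe_with_ci,
                              infer_sample_size, pca, pearson_screen,
                              posthoc_power_correlation, vif, zscore)


class TestZscore:
    def test_three_point_column(self):
        out = zscore(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["x"], [-1.0, 0.0, 1.0])

    def test_idempotence(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        once = zscore(df)
        pd.testing.assert_frame_equal(zscore(once), once, atol=1e-9)

    def test_missing_values_use_observed_only(self):
        # observed values (2, 4, 6): mean 4, sample SD 2
        out = zscore(pd.DataFrame({"x": [2.0, np.nan, 4.0, 6.0]}))
        np.testing.assert_allclose(out["x"], [-1.0, np.nan, 0.0, 1.0])

    def test_constant_column_named(self):
        with pytest.raises(ValidationError, match="flat"):
            zscore(pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]}))


class TestPearsonScreen:
    def test_collinear_pair(self):
        df = pd.DataFrame({"egg_sac": [1.0, 2, 3, 4], "x": [2.0, 4, 6, 8]})
        scr = pearson_screen(df)
        assert scr.r.loc["egg_sac", "x"] == pytest.approx(1.0)
        assert scr.p.loc["egg_sac", "x"] < 1e-6

    def test_t_transform_matches_r_p_pair(self):
        """r = 0.232 at n = 125 gives the two-sided p ~ 0.009."""
        t = 0.232 * np.sqrt(125 - 2) / np.sqrt(1 - 0.232**2)
        from scipy import stats

        p = 2 * stats.t.sf(t, 123)
        assert p == pytest.approx(0.009, abs=5e-4)

    def test_bonferroni_capping_and_family_size(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 4)),
                          columns=["egg_sac", "a", "b", "c"])
        scr = pearson_screen(df, family_size=9)
        resp = scr.response.set_index("variable")
        for v in ["a", "b", "c"]:
            expected = min(1.0, 9 * resp.loc[v, "p_uncorrected"])
            assert resp.loc[v, "p_bonferroni"] == pytest.approx(expected)

    def test_pairwise_complete_n(self):
        df = pd.DataFrame({"egg_sac": [1.0, 2, 3, 4, 5],
                           "x": [2.0, 1, np.nan, 3, 5]})
        scr = pearson_screen(df)
        assert scr.n.loc["egg_sac", "x"] == 4

    def test_short_pair_skipped_with_warning(self):
        df = pd.DataFrame({"egg_sac": [1.0, 2, 3, 4],
                           "x": [1.0, np.nan, np.nan, 2.0]})
        with pytest.warns(UserWarning, match="complete"):
            scr = pearson_screen(df)
        assert np.isnan(scr.r.loc["egg_sac", "x"])

    def test_planted_correlation_recovered(self):
        from salamet.synthio import HabitatSimConfig, simulate_habitat_table

        table = simulate_habitat_table(HabitatSimConfig(n_sites=5000, seed=11))
        scr = pearson_screen(table.select_dtypes("number"))
        # planted corr(egg_sac, pH) = -0.232, tolerance ~ CLT at n = 5000
        assert scr.r.loc["egg_sac", "pH"] == pytest.approx(-0.232, abs=0.04)


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert posthoc_power_correlation(0.0, 100) == pytest.approx(0.05, abs=1e-9)

    def test_moderate_effect_near_published_magnitude(self):
        # |r| = 0.232 at the table-implied n ~ 125 -> power ~ 0.74
        assert posthoc_power_correlation(0.232, 125) == pytest.approx(0.74, abs=0.02)

    def test_monotone_limit_in_r(self):
        powers = [posthoc_power_correlation(r, 30) for r in (0.1, 0.4, 0.7, 0.95)]
        assert all(np.diff(powers) > 0)
        assert powers[-1] > 0.99

    def test_domain_checks(self):
        with pytest.raises(ValidationError):
            posthoc_power_correlation(1.0, 50)
        with pytest.raises(ValidationError):
            posthoc_power_correlation(0.3, 3)


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame({"a": np.sin(2 * np.pi * t / n),
                           "b": np.cos(2 * np.pi * t / n),
                           "c": np.sin(4 * np.pi * t / n)})
        out = vif(df)
        np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-9)

    def test_duplicated_predictor_infinite(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
        out = vif(df)
        assert np.isinf(out["a"]) and np.isinf(out["b"])
        assert np.isfinite(out["c"])

    def test_planted_r2_three_quarters_gives_vif_4(self, rng):
        # construct y = x1 + x2 with noise tuned so R^2(y | x1, x2) = 0.75
        n = 20_000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        signal = x1 + x2  # variance 2
        noise = rng.normal(size=n) * np.sqrt(2 / 3)  # R2 = 2 / (2 + 2/3) = 0.75
        df = pd.DataFrame({"y": signal + noise, "x1": x1, "x2": x2})
        assert vif(df)["y"] == pytest.approx(4.0, rel=0.05)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        from statsmodels.tools import add_constant

        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        df["a"] += 0.8 * df["b"]
        ours = vif(df)
        X = add_constant(df.to_numpy())
        for j, col in enumerate(df.columns):
            ref = variance_inflation_factor(X, j + 1)
            assert ours[col] == pytest.approx(ref, rel=1e-8)


class TestPca:
    def test_perfectly_correlated_pair_single_axis(self):
        x = np.linspace(-1, 1, 20)
        df = zscore(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        res = pca(df)
        assert res.variance_pct["PC1"] == pytest.approx(100.0, abs=1e-9)

    def test_variance_percentages_sum_to_100(self, rng):
        df = zscore(pd.DataFrame(rng.normal(size=(30, 5))))
        res = pca(df)
        assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_independent_variables_spread_variance(self, rng):
        df = zscore(pd.DataFrame(rng.normal(size=(5000, 4))))
        res = pca(df)
        # 4 iid columns: each axis ~ 25%, Monte-Carlo tolerance ~ few %
        assert res.variance_pct.max() < 32.0

    def test_reconstruction_identity_and_orthonormal_loadings(self, rng):
        df = zscore(pd.DataFrame(rng.normal(size=(25, 4))))
        res = pca(df)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        centred = df.to_numpy() - df.to_numpy().mean(axis=0)
        np.testing.assert_allclose(recon, centred, atol=1e-9)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-9)

    def test_sign_convention_fixed(self, rng):
        df = zscore(pd.DataFrame(rng.normal(size=(30, 3))))
        res = pca(df)
        for comp in res.loadings.columns:
            v = res.loadings[comp].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_matches_sklearn_up_to_sign(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        df = zscore(pd.DataFrame(rng.normal(size=(40, 5))))
        res = pca(df)
        sk = SkPCA().fit(df.to_numpy())
        np.testing.assert_allclose(
            res.variance_pct.to_numpy(), 100 * sk.explained_variance_ratio_,
            atol=1e-9)
        np.testing.assert_allclose(np.abs(res.loadings.to_numpy().T),
                                   np.abs(sk.components_), atol=1e-9)


class TestDescribe:
    @pytest.mark.parametrize("mean,se,lo,hi", [
        (53.0, 2.7, 47.71, 58.29),
        (7.55, 0.10, 7.35, 7.75),
    ])
    def test_printed_interval_reproduced(self, mean, se, lo, hi):
        got_lo, got_hi = ci_from_summary(mean, se)
        assert round(got_lo, 2) == lo
        assert round(got_hi, 2) == hi

    def test_zero_se_collapses(self):
        out = describe_with_ci([5.0, 5.0, 5.0])
        assert out["ci_low"] == out["ci_high"] == out["mean"] == 5.0

    def test_describe_consistent_with_summary_ci(self, rng):
        x = rng.normal(10, 2, size=40)
        out = describe_with_ci(x)
        lo, hi = ci_from_summary(out["mean"], out["se"])
        assert (out["ci_low"], out["ci_high"]) == pytest.approx((lo, hi))

    def test_single_observation_rejected(self):
        with pytest.raises(ValidationError):
            describe_with_ci([1.0])


class TestInferSampleSize:
    def test_roundtrip_through_t_transform(self):
        from scipy import stats

        n_true = 80
        r = 0.3
        t = r * np.sqrt(n_true - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(t, n_true - 2)
        assert infer_sample_size(r, p) == pytest.approx(n_true, abs=1e-6)

    def test_domain_checks(self):
        with pytest.raises(ValidationError):
            infer_sample_size(0.0, 0.5)
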