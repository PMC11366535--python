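import numpy as np
import pandas as pd
import pytest
from scipy import stats

from carcasskit.pricemodel import (
    ModelSpec,
    anova_f_table,
    fit_fixed_effects_model,
    standardized_coefficients,
    _build_design,
)
from carcasskit.simgen import simulate_price_records


def _oracle_rss(x, y):
    """Projection-based residual sum of squares (SVD route, independent of lstsq)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    basis = u[:, s > s.max() * 1e-10]
    proj = basis @ (basis.T @ y)
    return float(((y - proj) ** 2).sum())


class TestFit:
    def test_exact_factor_response_has_zero_rss(self, rng):
        df = pd.DataFrame({"a": rng.integers(0, 4, 60), "b": rng.integers(0, 3, 60)})
        eff_a, eff_b = rng.normal(size=4), rng.normal(size=3)
        df["UP"] = eff_a[df.a] + eff_b[df.b]
        fit = fit_fixed_effects_model(df, ModelSpec(factors=("a", "b")))
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_single_factor_fits_group_means(self, rng):
        df = pd.DataFrame({"g": np.repeat([0, 1], [10, 14]), "UP": rng.normal(size=24)})
        spec = ModelSpec(factors=("g",))
        fit = fit_fixed_effects_model(df, spec)
        x, _, _ = _build_design(df, spec)
        fitted = x @ fit.coefficients.to_numpy()
        for g in (0, 1):
            assert np.allclose(fitted[df.g == g], df.UP[df.g == g].mean())

    def test_coefficients_match_pseudoinverse_oracle(self, rng):
        df = pd.DataFrame(
            {
                "a": rng.integers(0, 5, 200),
                "b": rng.integers(0, 4, 200),
                "x": rng.normal(size=200),
            }
        )
        df["UP"] = rng.normal(size=200)
        spec = ModelSpec(factors=("a", "b"), covariate="x")
        fit = fit_fixed_effects_model(df, spec)
        xmat, _, _ = _build_design(df, spec)
        oracle = np.linalg.pinv(xmat) @ df.UP.to_numpy()
        assert np.abs(fit.coefficients.to_numpy() - oracle).max() < 1e-8

    def test_single_level_factor_dropped_with_warning(self, rng):
        df = pd.DataFrame({"g": np.zeros(20, int), "x": rng.normal(size=20)})
        df["UP"] = df.x + rng.normal(size=20)
        with pytest.warns(UserWarning, match="one observed level"):
            fit = fit_fixed_effects_model(df, ModelSpec(factors=("g",), covariate="x"))
        assert "g" not in fit.term_columns

    def test_saturated_design_raises(self):
        df = pd.DataFrame({"g": [0, 1], "UP": [1.0, 2.0]})
        with pytest.raises(ValueError, match="residual"):
            fit_fixed_effects_model(df, ModelSpec(factors=("g",)))


class TestAnova:
    def test_one_way_f_equals_t_squared(self, rng):
        df = pd.DataFrame({"g": np.repeat([0, 1], [12, 15]), "UP": rng.normal(size=27)})
        tab = anova_f_table(df, ModelSpec(factors=("g",)))
        t, _ = stats.ttest_ind(df.UP[df.g == 0], df.UP[df.g == 1])
        assert tab.loc["g", "F"] == pytest.approx(t**2, abs=1e-10)

    def test_matches_nested_model_oracle(self, rng):
        df = simulate_price_records(240, 5, n_farm=6)
        spec = ModelSpec(covariate="iat", interaction_factor="MQ")
        tab = anova_f_table(df, spec)
        x, _, term_cols = _build_design(df, spec)
        y = df.UP.to_numpy()
        rss_full = _oracle_rss(x, y)
        rank_full = np.linalg.matrix_rank(x)
        df_resid = len(y) - rank_full
        for term, cols in term_cols.items():
            keep = np.ones(x.shape[1], bool)
            keep[cols] = False
            rss_red = _oracle_rss(x[:, keep], y)
            df_num = rank_full - np.linalg.matrix_rank(x[:, keep])
            f_oracle = ((rss_red - rss_full) / df_num) / (rss_full / df_resid)
            assert tab.loc[term, "F"] == pytest.approx(f_oracle, abs=1e-8)

    def test_f_invariant_to_relabeling_and_rescaling(self):
        df = simulate_price_records(200, 9, n_farm=5)
        spec = ModelSpec(factors=("date", "age", "sex", "farm", "MQ"), covariate="iat")
        base = anova_f_table(df, spec)
        mod = df.copy()
        mod["farm"] = mod["farm"].map(lambda v: f"farm_{(v * 7) % 5}")
        mod["iat"] = 3.5 * mod["iat"] - 40.0
        alt = anova_f_table(mod, spec)
        assert np.allclose(base["F"], alt["F"])

    def test_aliased_term_reported_absent(self, rng):
        df = pd.DataFrame({"a": rng.integers(0, 3, 40)})
        df["b"] = df["a"]  # perfectly aliased factor
        df["UP"] = rng.normal(size=40)
        tab = anova_f_table(df, ModelSpec(factors=("a", "b")))
        assert np.isnan(tab.loc["b", "F"]) and tab.loc["b", "df"] == 0


class TestStandardizedCoefficient:
    def test_pure_linear_response_gives_one(self, rng):
        df = pd.DataFrame(
            {
                "MQ": 4,
                "date": rng.integers(0, 3, 60),
                "age": rng.integers(0, 2, 60),
                "sex": rng.integers(0, 2, 60),
                "iat": rng.normal(size=60),
            }
        )
        df["UP"] = 2.0 * df["iat"]
        res = standardized_coefficients(df, 4, "iat")
        assert res["standardized_coefficient"] == pytest.approx(1.0)

    def test_null_covariate_near_zero(self):
        vals = []
        for s in range(20):
            df = simulate_price_records(500, 100 + s, iat_coefficient=0.0)
            vals.append(standardized_coefficients(df, 4, "iat")["standardized_coefficient"])
        assert abs(np.mean(vals)) < 0.1

    def test_matches_formula_oracle(self):
        df = simulate_price_records(300, 3)
        sub = df[df.MQ == 5]
        res = standardized_coefficients(df, 5, "iat")
        spec = ModelSpec(factors=("date", "age", "sex"), covariate="iat")
        x, labels, _ = _build_design(sub, spec)
        b = (np.linalg.pinv(x) @ sub.UP.to_numpy())[labels.index("iat")]
        expected = b * sub["iat"].std(ddof=1) / sub.UP.std(ddof=1)
        assert res["standardized_coefficient"] == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_affine_rescaling(self):
        df = simulate_price_records(300, 4)
        base = standardized_coefficients(df, 4, "iat")
        mod = df.copy()
        mod["iat"] = 5.0 * mod["iat"] + 100.0
        mod["UP"] = 0.2 * mod["UP"] - 300.0
        alt = standardized_coefficients(mod, 4, "iat")
        assert alt["standardized_coefficient"] == pytest.approx(
            base["standardized_coefficient"]
        )
        assert alt["t"] == pytest.approx(base["t"])

    def test_sign_recovery_under_positive_effect(self):
        hits = 0
        for s in range(100):
            df = simulate_price_records(500, 1000 + s, iat_coefficient=5.0)
            res = standardized_coefficients(df, 4, "iat")
            hits += res["standardized_coefficient"] > 0
        assert hits >= 95

    def test_zero_variance_covariate_raises(self):
        df = pd.DataFrame({"MQ": [4] * 10, "date": 0, "age": 0, "sex": 0, "iat": 1.0})
        df["UP"] = np.arange(10.0)
        with pytest.raises(ValueError, match="zero variance"):
            standardized_coefficients(df, 4, "iat")

    def test_empty_subset_raises(self):
        df = simulate_price_records(50, 0)
        with pytest.raises(ValueError, match="no records"):
            standardized_coefficients(df, 99, "iat")


def test_against_statsmodels_type_iii():
    """Independent oracle: statsmodels OLS with sum-coded interaction."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = simulate_price_records(300, 1, n_farm=8)
    tab = anova_f_table(df, ModelSpec(covariate="iat", interaction_factor="MQ"))
    m = smf.ols(
        "UP ~ C(date)+C(age)+C(sex)+C(farm)+C(MQ, Sum)+iat+C(MQ, Sum):iat", df
    ).fit()
    a3 = sm.stats.anova_lm(m, typ=3)
    pairs = {
        "date": "C(date)", "age": "C(age)", "sex": "C(sex)", "farm": "C(farm)",
        "MQ": "C(MQ, Sum)", "iat": "iat", "MQxiat": "C(MQ, Sum):iat",
    }
    for term, sm_term in pairs.items():
        assert tab.loc[term, "F"] == pytest.approx(a3.loc[sm_term, "F"], rel=1e-8)
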