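"""Design building, OLS, stepwise elimination, sequential ANOVA, LOOCV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdig import modeling
from pdig.modeling import Term, build_design, fit_ols, backward_stepwise, loocv_predict
from _oracles import loocv_leverage_oracle


def random_table(seed, n=60):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
            "c": rng.normal(size=n),
            "site": rng.integers(1, 4, n),
        }
    )


class TestBuildDesign:
    def test_empty_termset_intercept_only(self):
        X, mapping = build_design(random_table(0), [])
        assert list(X.columns) == ["intercept"]
        assert mapping == {}

    def test_identity_operand_interaction(self):
        data = random_table(1)
        data["ones"] = 1.0
        X, _ = build_design(data, [Term(("ones", "b"))])
        assert np.allclose(X["ones x b"], data["b"])

    def test_interaction_columns_match_oracle_products(self):
        data = random_table(2)
        terms = [Term(("a",)), Term(("a", "b")), Term(("b", "c"))]
        X, _ = build_design(data, terms)
        for u, v in [("a", "b"), ("b", "c")]:
            expected = [data[u][i] * data[v][i] for i in range(len(data))]
            assert np.allclose(X[f"{u} x {v}"], expected)

    def test_site_expands_to_reference_coded_indicators(self):
        data = random_table(3)
        X, mapping = build_design(data, [Term(("site",))])
        cols = mapping[Term(("site",))]
        assert len(cols) == data["site"].nunique() - 1
        assert set(X[cols].to_numpy().ravel()) <= {0.0, 1.0}

    def test_missing_source_column_named(self):
        with pytest.raises(ValueError, match="ghost"):
            build_design(random_table(4), [Term(("ghost",))])

    def test_categorical_interaction_rejected(self):
        with pytest.raises(ValueError, match="categorical"):
            build_design(random_table(5), [Term(("a", "site"))])


class TestFitOls:
    def test_noiseless_fit_r2_one(self):
        data = random_table(6)
        y = 1.0 + 2.0 * data["a"] - 3.0 * data["b"]
        X, mapping = build_design(data, [Term(("a",)), Term(("b",))])
        model = fit_ols(y, X, mapping, [Term(("a",)), Term(("b",))])
        assert model.r2 == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(model.residuals, 0, atol=1e-10)

    def test_coefficients_match_statsmodels(self):
        import statsmodels.api as sm

        data = random_table(7)
        rng = np.random.default_rng(7)
        y = 0.5 * data["a"] + data["b"] * data["c"] + rng.normal(size=len(data))
        terms = [Term(("a",)), Term(("b", "c"))]
        X, mapping = build_design(data, terms)
        model = fit_ols(y, X, mapping, terms)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(model.coefficients, ref.params, atol=1e-8)
        assert np.allclose(model.coef_se, ref.bse, atol=1e-8)
        assert model.adj_r2 == pytest.approx(ref.rsquared_adj, abs=1e-10)
        assert model.f_pvalue == pytest.approx(ref.f_pvalue, abs=1e-10)

    def test_overall_test_calibrated_under_null(self):
        hits = 0
        reps = 1000
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            data = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
            y = rng.normal(size=40)
            terms = modeling.main_effects(["a", "b", "c"])
            X, mapping = build_design(data, terms)
            if fit_ols(y, X, mapping, terms).f_pvalue < 0.05:
                hits += 1
        assert abs(hits / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_adjusted_r2_formula_and_bound(self):
        data = random_table(8)
        rng = np.random.default_rng(8)
        y = data["a"] + rng.normal(size=len(data))
        terms = modeling.main_effects(["a", "b"])
        X, mapping = build_design(data, terms)
        m = fit_ols(y, X, mapping, terms)
        n, p = m.n, m.n_slopes
        assert m.adj_r2 == pytest.approx(1 - (1 - m.r2) * (n - 1) / (n - p - 1))
        assert m.adj_r2 <= m.r2

    def test_rank_deficiency_names_offenders(self):
        data = random_table(9)
        data["dup"] = data["a"]
        terms = modeling.main_effects(["a", "dup"])
        X, mapping = build_design(data, terms)
        with pytest.raises(np.linalg.LinAlgError, match="dup"):
            fit_ols(data["b"], X, mapping, terms)


class TestSequentialAnova:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_decomposition_identities(self, seed):
        rng = np.random.default_rng(seed)
        data = random_table(seed)
        y = (
            data["a"]
            - 0.5 * data["b"]
            + 0.3 * data["a"] * data["c"]
            + rng.normal(size=len(data))
        )
        terms = [Term(("a",)), Term(("b",)), Term(("site",)), Term(("a", "c"))]
        X, mapping = build_design(data, terms)
        m = fit_ols(y, X, mapping, terms)
        # sum of per-term percent explained equals 100*R^2
        assert m.anova["pct_explained"].sum() == pytest.approx(100 * m.r2, abs=1e-8)
        # SS conservation: term SS + residual SS = total SS
        ss_total = np.sum((y - y.mean()) ** 2)
        ss_resid = float(m.residuals @ m.residuals)
        assert m.anova["sum_sq"].sum() + ss_resid == pytest.approx(ss_total, abs=1e-8)

    def test_single_term_model_pct_equals_r2(self):
        data = random_table(10)
        rng = np.random.default_rng(10)
        y = data["a"] + rng.normal(size=len(data))
        terms = [Term(("a",))]
        X, mapping = build_design(data, terms)
        m = fit_ols(y, X, mapping, terms)
        assert m.anova["pct_explained"].iloc[0] == pytest.approx(100 * m.r2, abs=1e-10)

    def test_orthogonal_predictors_order_invariant(self):
        n = 64
        # orthogonal design: centered +/-1 patterns
        data = pd.DataFrame(
            {
                "a": np.tile([1.0, -1.0], n // 2),
                "b": np.repeat([1.0, -1.0], n // 2),
            }
        )
        rng = np.random.default_rng(11)
        y = data["a"] + 2 * data["b"] + rng.normal(size=n)
        ss = {}
        for order in (["a", "b"], ["b", "a"]):
            terms = modeling.main_effects(order)
            X, mapping = build_design(data, terms)
            m = fit_ols(y, X, mapping, terms)
            for t in order:
                ss.setdefault(t, []).append(m.anova.loc[t, "sum_sq"])
        for t, vals in ss.items():
            assert vals[0] == pytest.approx(vals[1], abs=1e-8)


class TestBackwardStepwise:
    def test_trace_reproducible(self):
        data = random_table(12)
        rng = np.random.default_rng(12)
        y = data["a"] + rng.normal(size=len(data))
        terms = modeling.main_effects(["a", "b", "c"]) + [Term(("b", "c"))]
        m1 = backward_stepwise(y, data, terms)
        m2 = backward_stepwise(y, data, terms)
        assert m1.stepwise_trace == m2.stepwise_trace
        assert [t.name for t in m1.terms] == [t.name for t in m2.terms]

    def test_informative_kept_noise_dropped(self):
        keep_hits, drop_hits = 0, 0
        for seed in range(50):
            rng = np.random.default_rng(seed + 10_000)
            data = random_table(seed)
            y = 1.2 * data["a"] + rng.normal(size=len(data))  # strong signal on a
            m = backward_stepwise(y, data, modeling.main_effects(["a", "b", "c"]))
            names = [t.name for t in m.terms]
            keep_hits += "a" in names
            drop_hits += ("b" not in names) and ("c" not in names)
        assert keep_hits >= 45
        assert drop_hits >= 26

    def test_all_noise_model_shrinks(self):
        shrunk = 0
        for seed in range(30):
            rng = np.random.default_rng(20_000 + seed)
            data = random_table(1000 + seed, n=80)
            y = pd.Series(rng.normal(size=80))
            m = backward_stepwise(y, data, modeling.main_effects(["a", "b", "c"]))
            shrunk += len(m.terms) < 3
        assert shrunk > 15

    def test_collinear_terms_pre_pruned(self):
        data = random_table(13)
        data["dup"] = data["a"]
        rng = np.random.default_rng(13)
        y = data["a"] + rng.normal(size=len(data))
        with pytest.warns(UserWarning, match="collinear"):
            m = backward_stepwise(y, data, modeling.main_effects(["a", "dup", "b"]))
        assert Term(("dup",)) not in m.terms


class TestThreeModels:
    def test_combined_initial_set_is_superset(self):
        rng = np.random.default_rng(14)
        data = pd.DataFrame(
            rng.normal(size=(80, 5)), columns=["img1", "img2", "snp1", "snp2", "cov"]
        )
        y = data["img1"] + data["snp1"] + rng.normal(size=80)
        models = modeling.build_three_models(
            y, data, ["img1", "img2"], ["snp1", "snp2"], ["cov"],
            categorical=frozenset(), interaction_cap=6,
        )
        assert set(models) == {"A", "B", "C"}
        for m in models.values():
            assert m.anova is not None

    def test_empty_feature_sets_rejected(self):
        data = random_table(15)
        with pytest.raises(ValueError, match="non-empty"):
            modeling.build_three_models(
                data["a"], data, [], ["b"], ["c"], categorical=frozenset()
            )


class TestLoocv:
    def test_noiseless_truth_perfect_prediction(self):
        data = random_table(16)
        y = 2.0 + data["a"] - data["b"]
        cv = loocv_predict(y, data, modeling.main_effects(["a", "b"]))
        assert cv.rmse < 1e-6
        assert cv.pearson_r == pytest.approx(1.0, abs=1e-6)
        assert cv.n_folds == len(data)

    def test_matches_leverage_closed_form(self):
        data = random_table(17)
        rng = np.random.default_rng(17)
        y = data["a"] + 0.5 * data["b"] + rng.normal(size=len(data))
        terms = modeling.main_effects(["a", "b", "c"])
        cv = loocv_predict(y, data, terms)
        X, _ = build_design(data, terms)
        expected = loocv_leverage_oracle(X.to_numpy(float), y.to_numpy(float))
        assert np.allclose(cv.predictions, expected, atol=1e-8)

    def test_sample_size_guard(self):
        data = random_table(18).iloc[:5]
        with pytest.raises(ValueError, match="LOOCV"):
            loocv_predict(data["a"], data, modeling.main_effects(["b", "c"]))
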