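"""Best-subset AIC selection: oracles, exactness and diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenodelta.subset import (
    BestSubsetRegressor,
    RankDeficientError,
    aic_gaussian,
    best_subset,
    effect_contrast,
    ols_fit,
    vif,
)

# frozen from the univariate closed-form normal equations (4 points)
OLS4_X = np.array([0.0, 1.0, 2.0, 4.0])
OLS4_Y = np.array([1.0, 2.0, 2.5, 5.0])
OLS4_SLOPE = 0.9857142857142858
OLS4_INTERCEPT = 0.8999999999999999

# frozen from an independent evaluation of n·ln(rss/n) + n(ln2π+1) + 2(k+2)
AIC_RSS10_N100_K3 = 63.529197341529965


class TestOlsFit:
    def test_noiseless_recovery(self, rng):
        X = rng.standard_normal((40, 3))
        y = 1.0 + X @ [2.0, -1.0, 0.5]
        fit = ols_fit(X, y)
        assert np.allclose(fit.beta, [1.0, 2.0, -1.0, 0.5], atol=1e-10)
        assert fit.rss < 1e-10

    def test_univariate_closed_form(self):
        fit = ols_fit(OLS4_X.reshape(-1, 1), OLS4_Y, names=["x"])
        assert fit.beta["x"] == pytest.approx(OLS4_SLOPE, abs=1e-12)
        assert fit.beta["intercept"] == pytest.approx(OLS4_INTERCEPT, abs=1e-12)

    def test_permutation_invariance(self, rng):
        X = rng.standard_normal((30, 2))
        y = X @ [1.0, 2.0] + rng.standard_normal(30)
        perm = rng.permutation(30)
        a, b = ols_fit(X, y), ols_fit(X[perm], y[perm])
        assert np.allclose(a.beta, b.beta, atol=1e-12)
        assert np.allclose(a.se, b.se, atol=1e-12)
        assert a.aic == pytest.approx(b.aic, abs=1e-9)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        X = rng.standard_normal((60, 4))
        y = X @ [1.0, 0.0, -0.5, 0.2] + rng.standard_normal(60)
        fit = ols_fit(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.beta, ref.params, atol=1e-10)
        assert np.allclose(fit.se, ref.bse, atol=1e-10)
        assert fit.r2_adj == pytest.approx(ref.rsquared_adj, abs=1e-10)
        # statsmodels does not count the error variance as a parameter
        assert fit.aic == pytest.approx(ref.aic + 2.0, abs=1e-8)

    def test_rank_deficiency_names_column(self, rng):
        c = rng.standard_normal(20)
        df = pd.DataFrame({"a": c, "twice_a": 2 * c})
        with pytest.raises(RankDeficientError, match="twice_a"):
            ols_fit(df, rng.standard_normal(20))


class TestAic:
    def test_formula_oracle(self):
        assert aic_gaussian(10.0, 100, 3) == pytest.approx(AIC_RSS10_N100_K3, abs=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(rss=st.floats(1e-3, 1e6), n=st.integers(5, 10_000), k=st.integers(0, 20))
    def test_useless_predictor_penalty_is_two(self, rss, n, k):
        assert aic_gaussian(rss, n, k + 1) - aic_gaussian(rss, n, k) == pytest.approx(2.0)

    def test_monotone_in_rss(self):
        assert aic_gaussian(5.0, 50, 2) < aic_gaussian(6.0, 50, 2)

    def test_zero_rss_sentinel(self):
        with pytest.warns(UserWarning, match="perfect fit"):
            assert aic_gaussian(0.0, 50, 2) == -math.inf


class TestVif:
    def test_orthogonal_design_all_ones(self):
        n = 64
        X = np.column_stack([np.tile([1.0, -1.0], n // 2),
                             np.repeat([1.0, -1.0], n // 2)])
        assert np.allclose(vif(X), 1.0, atol=1e-12)

    def test_bivariate_closed_form(self, rng):
        # two predictors with sample correlation forced to exactly 0.6
        a = rng.standard_normal(200)
        b = rng.standard_normal(200)
        a = (a - a.mean()) / a.std()
        res = b - a * (a @ b) / (a @ a)
        res = (res - res.mean()) / res.std()
        x2 = 0.6 * a + math.sqrt(1 - 0.36) * res
        X = np.column_stack([a, x2])
        assert np.allclose(vif(X), 1.0 / (1.0 - 0.36), atol=1e-9)

    def test_scale_invariance(self, rng):
        X = rng.standard_normal((50, 3))
        scaled = X * np.array([10.0, 0.01, 3.0])
        assert np.allclose(vif(X), vif(scaled), atol=1e-9)

    def test_perfect_collinearity_flags_inf(self, rng):
        c = rng.standard_normal(30)
        X = np.column_stack([c, 2 * c, rng.standard_normal(30)])
        v = vif(X)
        assert np.isinf(v.iloc[0]) and np.isinf(v.iloc[1])

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        X = rng.standard_normal((80, 4)) @ rng.standard_normal((4, 4))
        Xi = sm.add_constant(X)
        ref = [variance_inflation_factor(Xi, j) for j in range(1, 5)]
        assert np.allclose(vif(X), ref, atol=1e-8)


class TestBestSubset:
    def test_equals_exhaustive_on_random_instances(self, random_regression):
        for seed in range(12):
            df, cand, _ = random_regression(seed, p=int(6 + seed % 5))
            bb = best_subset(cand, ["forced0"], df, "y", method="branch_and_bound")
            ex = best_subset(cand, ["forced0"], df, "y", method="exhaustive")
            assert bb.selected == ex.selected
            assert bb.fit.aic == pytest.approx(ex.fit.aic, abs=1e-9)

    def test_forcing_contract(self, random_regression):
        for seed in (0, 1, 2):
            df, cand, _ = random_regression(seed)
            model = best_subset(cand, ["forced0"], df, "y")
            assert "forced0" in model.selected
            assert set(model.forced) <= set(model.selected)

    def test_true_predictor_recovered_noise_mostly_excluded(self):
        # one real effect (beta = 0.5) among nine noise candidates; AIC keeps
        # the real one essentially always and admits each noise candidate
        # with probability ~P(chi2_1 > 2) ~ 0.157
        reps, n = 60, 5000
        r = np.random.default_rng(314)
        true_in = 0
        noise_in = 0
        for _ in range(reps):
            X = r.standard_normal((n, 10))
            y = 0.5 * X[:, 0] + r.standard_normal(n)
            df = pd.DataFrame(X, columns=[f"c{j}" for j in range(10)])
            df["y"] = y
            df["dage"] = r.standard_normal(n)
            model = best_subset([f"c{j}" for j in range(10)], ["dage"], df, "y")
            true_in += "c0" in model.selected
            noise_in += len(set(model.selected) - {"dage", "c0"})
        assert true_in == reps
        # 9 noise candidates/rep at ~0.157 each: mean inclusions/rep ~ 1.4
        assert noise_in / reps < 3.0

    def test_tie_break_prefers_fewer_then_lexicographic(self):
        from phenodelta.subset import _subset_better
        best = (100.0, 3, ("b",))
        assert _subset_better(100.0, 2, ("z",), best)       # fewer predictors wins
        assert _subset_better(100.0, 3, ("a",), best)       # then lexicographic
        assert not _subset_better(100.0, 3, ("c",), best)
        assert _subset_better(99.0, 5, ("v", "w"), best)    # AIC dominates both

    def test_uninformative_candidates_yield_forced_only_model(self, rng):
        # outcome constructed exactly orthogonal to both candidates: every
        # subset has identical RSS and the penalty picks the smallest model
        n = 50
        X = rng.standard_normal((n, 2))
        y0 = rng.standard_normal(n)
        Z = np.column_stack([np.ones(n), X])
        y = y0 - Z @ np.linalg.lstsq(Z, y0, rcond=None)[0]
        df = pd.DataFrame({"c1": X[:, 0], "c2": X[:, 1], "y": y})
        model = best_subset(["c1", "c2"], [], df, "y", method="exhaustive")
        assert model.selected == []

    def test_affine_rescaling_invariance(self, random_regression):
        df, cand, _ = random_regression(3, p=7)
        base = best_subset(cand, ["forced0"], df, "y")
        scaled = df.copy()
        for j, c in enumerate(cand):
            scaled[c] = df[c] * (j + 2.0) - 1.5 * j
        rescaled = best_subset(cand, ["forced0"], scaled, "y")
        assert rescaled.selected == base.selected

    def test_refuses_too_many_candidates(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 32)),
                          columns=[f"c{j}" for j in range(32)])
        df["y"] = rng.standard_normal(50)
        with pytest.raises(ValueError, match="exceed"):
            best_subset([f"c{j}" for j in range(31)], [], df, "y")

    def test_overlapping_forced_rejected(self, random_regression):
        df, cand, _ = random_regression(0)
        with pytest.raises(ValueError, match="disjoint"):
            best_subset(cand, [cand[0]], df, "y")


class TestEffectContrast:
    def test_four_point_diet_contrasts(self):
        from phenodelta.subset import OlsFit
        beta = pd.Series({"intercept": 0.0, "diet5": 0.0921, "diet16": 0.0941})
        fit = OlsFit(beta=beta, se=beta * 0, p=beta * 0, rss=1.0, tss=1.0,
                     n=10, k=2, r2_adj=0.0, aic=0.0)
        assert effect_contrast(fit, "diet5", 4) == pytest.approx(0.3684)
        assert effect_contrast(fit, "diet16", 4) == pytest.approx(0.3764)

    def test_null_contrast_and_unknown_predictor(self, rng):
        fit = ols_fit(rng.standard_normal((20, 2)), rng.standard_normal(20),
                      names=["a", "b"])
        assert effect_contrast(fit, "a", 0.0) == 0.0
        with pytest.raises(KeyError, match="ghost"):
            effect_contrast(fit, "ghost", 1.0)


class TestRegressorEstimator:
    def test_fit_predict_roundtrip(self, random_regression):
        df, cand, _ = random_regression(8, p=6)
        X = df[cand + ["forced0"]]
        est = BestSubsetRegressor(forced=["forced0"]).fit(X, df["y"])
        assert "forced0" in est.selected_
        manual = est.intercept_ + sum(
            est.coef_[c] * X[c].to_numpy() for c in est.selected_)
        assert np.allclose(est.predict(X), manual, atol=1e-10)
        assert est.aic_ == pytest.approx(est.model_.fit.aic)

    def test_sklearn_clone(self):
        from sklearn.base import clone
        est = BestSubsetRegressor(forced=["dage"], method="exhaustive")
        assert clone(est).get_params() == est.get_params()
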