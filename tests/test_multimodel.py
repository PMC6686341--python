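import math

import numpy as np
import pandas as pd
import pytest

from firerefugia.multimodel import (
    akaike_weights,
    enumerate_candidates,
    fit_ols_aicc,
    model_average,
    run_model_selection,
    screen_collinearity,
    standardize,
)


class TestScreening:
    def test_identical_columns_flagged(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"a": x, "b": x, "c": np.cos(x)})
        rep = screen_collinearity(df)
        assert rep.spearman.loc["a", "b"] == pytest.approx(1.0)
        assert math.isinf(rep.vif["a"]) and math.isinf(rep.vif["b"])
        assert ("a" in rep.dropped) or ("b" in rep.dropped)

    def test_orthogonal_columns_unit_vif(self):
        df = pd.DataFrame(
            {
                "a": [1, 1, -1, -1.0],
                "b": [1, -1, 1, -1.0],
                "c": [1, -1, -1, 1.0],
            }
        )
        rep = screen_collinearity(df)
        assert all(abs(v - 1.0) < 1e-10 for v in rep.vif)
        assert rep.retained == ["a", "b", "c"]

    def test_monotone_transform_has_unit_spearman(self):
        x = np.linspace(-2, 2, 15)
        df = pd.DataFrame({"x": x, "x3": x**3, "z": np.sin(5 * x)})
        rep = screen_collinearity(df)
        assert rep.spearman.loc["x", "x3"] == pytest.approx(1.0)


class TestStandardize:
    def test_closed_form(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, stats_ = standardize(df)
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])
        assert stats_.loc["a", "mean"] == 2.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5, 3, size=(20, 3)), columns=list("abc"))
        once, _ = standardize(df)
        twice, _ = standardize(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_moments(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(-10, 10, size=(30, 4)))
        out, _ = standardize(df)
        assert np.all(np.abs(out.mean()) < 1e-12)
        np.testing.assert_allclose(out.std(ddof=1), 1.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestEnumeration:
    @pytest.mark.parametrize("v, s, expected", [(3, 3, 63), (1, 1, 1), (2, 2, 8)])
    def test_counts(self, v, s, expected):
        assert len(enumerate_candidates(v, s)) == expected

    def test_one_scale_per_variable(self):
        for terms in enumerate_candidates(["h", "c"], ["a", "b"]):
            vars_used = [t.rsplit("_", 1)[0] for t in terms]
            assert len(vars_used) == len(set(vars_used))

    def test_null_model_excluded_and_unique(self):
        models = enumerate_candidates(3, 3)
        assert () not in models
        assert len(set(models)) == len(models)


class TestOLS:
    def test_normal_equations_hand_solution(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        X = pd.DataFrame({"x": x})
        m = fit_ols_aicc(y, X, ("x",))
        # closed-form 2x2 solve
        n = 5
        sxx = (x**2).sum() - x.sum() ** 2 / n
        sxy = (x * y).sum() - x.sum() * y.sum() / n
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        assert m.coef["x"] == pytest.approx(slope)
        assert m.coef["intercept"] == pytest.approx(intercept)
        assert m.k == 3  # intercept + slope + variance

    def test_perfect_fit_dominates(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=12), "b": rng.normal(size=12)})
        y = 2.0 * X["a"].to_numpy()  # exactly linear in a, no noise
        models = [fit_ols_aicc(y, X, t) for t in [("a",), ("b",), ("a", "b")]]
        w = akaike_weights(np.array([m.aicc for m in models]))
        assert models[0].rss == pytest.approx(0.0, abs=1e-20)
        assert w[0] > 0.99

    def test_duplicate_model_same_aicc(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=10)})
        y = rng.normal(size=10)
        m1 = fit_ols_aicc(y, X, ("a",))
        m2 = fit_ols_aicc(y, X, ("a",))
        assert m1.aicc == m2.aicc

    def test_small_n_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="too small"):
            fit_ols_aicc(np.zeros(4), X, ("a",))


class TestWeightsAndAveraging:
    def test_weights_sum_and_shift_invariance(self):
        rng = np.random.default_rng(4)
        aicc = rng.uniform(100, 140, size=63)
        w = akaike_weights(aicc)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, akaike_weights(aicc + 57.3), atol=1e-12)

    def test_single_model_average_is_identity(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=15)})
        y = 0.5 * X["a"].to_numpy() + rng.normal(0, 0.1, 15)
        m = fit_ols_aicc(y, X, ("a",))
        res = model_average([m])
        assert res.table.loc["a", "estimate"] == pytest.approx(m.coef["a"])
        assert m.weight == pytest.approx(1.0)

    def test_equal_weight_absent_term_halves(self):
        # two models with identical AICc; a term present only in one
        # contributes half its coefficient to the full average
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        y = 1.0 + rng.normal(0, 0.5, 20)
        m1 = fit_ols_aicc(y, X, ("a",))
        m2 = fit_ols_aicc(y, X, ("a",))
        m2 = type(m2)(terms=(), k=2, loglik=m1.loglik, aicc=m1.aicc,
                      coef={"intercept": y.mean()}, coef_se={"intercept": 0.1}, rss=m1.rss)
        res = model_average([m1, m2], mode="full")
        assert res.table.loc["a", "estimate"] == pytest.approx(m1.coef["a"] / 2)

    def test_full_shrinks_relative_to_conditional(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=["a", "b", "c"])
        y = 0.8 * X["a"].to_numpy() + rng.normal(0, 1.0, 25)
        terms_sets = [("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c")]
        models = [fit_ols_aicc(y, X, t) for t in terms_sets]
        full = model_average(models, mode="full").table
        cond = model_average(models, mode="conditional").table
        for t in ["a", "b", "c"]:
            assert abs(full.loc[t, "estimate"]) <= abs(cond.loc[t, "estimate"]) + 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            model_average([])


def test_run_model_selection_end_to_end():
    rng = np.random.default_rng(8)
    n = 32
    cols = {f"{v}_{s}": rng.normal(size=n)
            for v in ("veg", "cheat", "elev") for s in ("a", "b", "c")}
    X = pd.DataFrame(cols)
    y = 0.5 * X["veg_a"].to_numpy() - 0.5 * X["cheat_b"].to_numpy() + rng.normal(0, 0.3, n)
    ranked, avg, fitted = run_model_selection(
        y, X, variables=["veg", "cheat", "elev"], scales=["a", "b", "c"]
    )
    assert len(fitted) == 63
    assert ranked["weight"].sum() == pytest.approx(1.0, abs=1e-9)
    assert avg.table.loc["veg_a", "estimate"] > 0.3
    assert avg.table.loc["cheat_b", "estimate"] < -0.3
    # significance matches the CI-excludes-zero rule
    sig = (avg.table["lower"] > 0) | (avg.table["upper"] < 0)
    assert sig["veg_a"] and sig["cheat_b"]
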