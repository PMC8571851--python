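"""Ordered-logit estimation: oracles, invariances, diagnostics, OLS."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.miscmodels.ordinal_model import OrderedModel

from conftest import irls_logit
from rdhealth.exceptions import ConfigError, SeparationError
from rdhealth.ordinal import (ModelSpec, OrdinalFit, fit_ols,
                              fit_ordered_logit, odds_ratio, predict_probs,
                              pseudo_r2, vif_tolerance)
from rdhealth.ordinal import _nll_grad


def _binary_dataset(seed, n=200, p=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(scale=0.8, size=p)
    y = (X @ beta + rng.logistic(size=n) > 0).astype(int)
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    df["y"] = y
    return df


@pytest.mark.parametrize("seed", range(5))
def test_binary_reduction_matches_irls_oracle(seed):
    """With 2 categories the fit equals an independently coded binary logit."""
    df = _binary_dataset(seed)
    fit = fit_ordered_logit(df, ModelSpec("y", ["x0", "x1", "x2"]))
    icept, slopes = irls_logit(df[["x0", "x1", "x2"]].to_numpy(), df["y"])
    np.testing.assert_allclose(
        [fit.coefficients[f"x{j}"] for j in range(3)], slopes, atol=1e-6)
    assert fit.cutpoints[0] == pytest.approx(-icept, abs=1e-6)


def test_matches_statsmodels_ordered_model():
    """Independent cross-check against statsmodels on a 4-category outcome."""
    rng = np.random.default_rng(5)
    n = 1500
    X = rng.normal(size=(n, 3))
    lat = X @ np.array([0.8, -0.5, 0.3]) + rng.logistic(size=n)
    y = np.searchsorted(np.quantile(lat, [0.2, 0.55, 0.85]), lat)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["y"] = y
    fit = fit_ordered_logit(df, ModelSpec("y", ["a", "b", "c"]))
    sm_res = OrderedModel(y, X, distr="logit").fit(
        method="bfgs", gtol=1e-8, disp=0)
    np.testing.assert_allclose(
        [fit.coefficients[k] for k in "abc"], sm_res.params[:3], atol=1e-4)
    np.testing.assert_allclose(
        fit.cutpoints,
        np.cumsum(np.concatenate([[sm_res.params[3]],
                                  np.exp(sm_res.params[4:])])),
        atol=1e-4)
    assert fit.log_likelihood >= sm_res.llf - 1e-6


def test_shift_invariance():
    """Adding a constant to predictors shifts cutpoints, not coefficients."""
    df = _binary_dataset(9, n=400)
    rng = np.random.default_rng(9)
    df["y"] = np.searchsorted([-1.0, 0.5], rng.normal(size=len(df)))
    spec = ModelSpec("y", ["x0", "x1", "x2"])
    base = fit_ordered_logit(df, spec)
    shifted = df.copy()
    shifted[["x0", "x1", "x2"]] += 5.0
    moved = fit_ordered_logit(shifted, spec)
    for k in ("x0", "x1", "x2"):
        assert moved.coefficients[k] == pytest.approx(base.coefficients[k],
                                                      abs=1e-8)
    beta_sum = sum(base.coefficients.values())
    np.testing.assert_allclose(moved.cutpoints, base.cutpoints + 5.0 * beta_sum,
                               atol=1e-7)
    np.testing.assert_allclose(
        predict_probs(moved, shifted), predict_probs(base, df), atol=1e-8)


def test_local_optimum_beats_random_perturbations(small_table):
    spec = ModelSpec("mh", ["trust", "fair", "age", "education"])
    fit = fit_ordered_logit(small_table, spec)
    X = small_table[spec.predictors].to_numpy(dtype=float)
    y = np.searchsorted(fit.outcome_categories, small_table["mh"].to_numpy())
    theta_hat = fit.params
    nll_hat, _ = _nll_grad(theta_hat, X, y, len(fit.outcome_categories))
    rng = np.random.default_rng(0)
    for _ in range(100):
        theta = theta_hat + rng.normal(scale=0.05, size=theta_hat.size)
        if np.any(np.diff(theta[len(spec.predictors):]) <= 0):
            continue
        nll, _ = _nll_grad(theta, X, y, len(fit.outcome_categories))
        assert nll >= nll_hat - 1e-9


class TestPredictProbs:
    def test_zero_model_splits_evenly(self):
        fit = OrdinalFit(
            coefficients={"x": 0.0}, cutpoints=np.array([0.0]),
            vcov=pd.DataFrame(np.eye(2)), se=pd.Series([1.0, 1.0]),
            log_likelihood=0.0, null_log_likelihood=-1.0, n_obs=2,
            outcome="y", outcome_categories=np.array([0, 1]),
            predictor_names=["x"])
        P = predict_probs(fit, pd.DataFrame({"x": [0.0, 0.0]}))
        np.testing.assert_allclose(P, 0.5, atol=1e-15)

    def test_extreme_linear_predictor_concentrates_top(self):
        fit = OrdinalFit(
            coefficients={"x": 1.0}, cutpoints=np.array([-1.0, 0.0, 1.0]),
            vcov=pd.DataFrame(np.eye(4)), se=pd.Series(np.ones(4)),
            log_likelihood=0.0, null_log_likelihood=-1.0, n_obs=1,
            outcome="y", outcome_categories=np.arange(4),
            predictor_names=["x"])
        P = predict_probs(fit, pd.DataFrame({"x": [60.0]}))
        assert P[0, -1] == pytest.approx(1.0, abs=1e-12)

    def test_rows_sum_to_one(self, small_table):
        fit = fit_ordered_logit(
            small_table, ModelSpec("ph", ["trust", "age"], fixed_effect="province"))
        P = predict_probs(fit, small_table.head(100))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_missing_predictor_raises(self, small_table):
        fit = fit_ordered_logit(small_table, ModelSpec("ph", ["trust", "age"]))
        with pytest.raises(KeyError, match="trust"):
            predict_probs(fit, small_table[["age"]])


def test_pseudo_r2_null_model_is_zero(small_table):
    fit = fit_ordered_logit(small_table, ModelSpec("mh", []))
    assert pseudo_r2(fit) == pytest.approx(0.0, abs=1e-10)


def test_pseudo_r2_in_unit_interval(small_table):
    fit = fit_ordered_logit(small_table, ModelSpec("mh", ["trust", "fair", "age"]))
    assert 0.0 < fit.pseudo_r2 < 1.0


def test_odds_ratio_values():
    assert odds_ratio(0.0) == pytest.approx(1.0)
    assert round(odds_ratio(-0.962), 3) == 0.382
    assert round(odds_ratio(-0.280), 3) == 0.756


def test_robust_se_differ_from_classical(small_table):
    spec = ModelSpec("mh", ["trust", "age"], robust_se=False)
    plain = fit_ordered_logit(small_table, spec)
    robust = fit_ordered_logit(
        small_table, ModelSpec("mh", ["trust", "age"], robust_se=True))
    assert plain.coefficients == pytest.approx(robust.coefficients)
    assert not np.allclose(plain.se.to_numpy(), robust.se.to_numpy())
    # same order of magnitude though
    assert np.all(robust.se.to_numpy() / plain.se.to_numpy() < 2.0)


class TestErrors:
    def test_single_category_outcome(self, small_table):
        df = small_table.copy()
        df["mh"] = 3
        with pytest.raises(ValueError, match="single observed category"):
            fit_ordered_logit(df, ModelSpec("mh", ["trust"]))

    def test_zero_variance_predictor(self, small_table):
        df = small_table.copy()
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="flat"):
            fit_ordered_logit(df, ModelSpec("mh", ["trust", "flat"]))

    def test_outcome_in_predictors(self):
        with pytest.raises(ConfigError):
            ModelSpec("mh", ["mh", "trust"])

    def test_perfect_separation(self):
        df = pd.DataFrame({"x": np.linspace(-2, 2, 80)})
        df["y"] = (df["x"] > 0).astype(int)
        with pytest.raises(SeparationError):
            fit_ordered_logit(df, ModelSpec("y", ["x"]))


class TestVIF:
    def test_orthogonal_predictors(self):
        df = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1]},
                          dtype=float)
        res = vif_tolerance(df, ["a", "b"])
        for v in res.values():
            assert v["vif"] == pytest.approx(1.0, abs=1e-12)
            assert v["tolerance"] == pytest.approx(1.0, abs=1e-12)

    def test_exact_bivariate_correlation(self):
        # columns built so the sample correlation is exactly 0.6
        rho = 0.6
        u = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        v = v - v @ u / (u @ u) * u  # orthogonalize
        v /= np.linalg.norm(v)
        u /= np.linalg.norm(u)
        df = pd.DataFrame({"a": u, "b": rho * u + np.sqrt(1 - rho**2) * v})
        res = vif_tolerance(df, ["a", "b"])
        assert res["a"]["vif"] == pytest.approx(1 / (1 - 0.36), abs=1e-9)
        assert res["b"]["vif"] == pytest.approx(1.5625, abs=1e-9)

    def test_duplicated_predictor_flagged_infinite(self, small_table):
        df = small_table.copy()
        df["trust2"] = df["trust"]
        res = vif_tolerance(df, ["trust", "trust2", "age"])
        assert np.isinf(res["trust"]["vif"]) and res["trust"]["collinear"]

    def test_survey_predictors_not_collinear(self, small_table):
        res = vif_tolerance(small_table,
                            ["trust", "fair", "age", "education", "urban"])
        assert all(v["vif"] < 2.0 for v in res.values())

    def test_errors(self, small_table):
        with pytest.raises(ValueError, match="at least 2"):
            vif_tolerance(small_table, ["trust"])
        df = small_table.copy()
        df["flat"] = 0.0
        with pytest.raises(ValueError, match="flat"):
            vif_tolerance(df, ["trust", "flat"])


class TestOLS:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["y"] = 2.0 + 3.0 * df["x"]
        fit = fit_ols(df, ModelSpec("y", ["x"]))
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.coefficients["x"] == pytest.approx(3.0, abs=1e-10)

    def test_intercept_only_returns_mean(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 6.0]})
        fit = fit_ols(df, ModelSpec("y", []))
        assert fit.coefficients["const"] == pytest.approx(3.0)

    def test_slope_recovery_within_two_se(self):
        rng = np.random.default_rng(4)
        n = 5000
        df = pd.DataFrame({"x": rng.normal(size=n)})
        df["y"] = 1.0 - 0.7 * df["x"] + rng.normal(scale=2.0, size=n)
        fit = fit_ols(df, ModelSpec("y", ["x"], robust_se=True))
        assert abs(fit.coefficients["x"] - (-0.7)) < 2 * fit.se["x"]

    def test_singular_design_raises(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        df["x2"] = 2 * df["x"]
        df["y"] = [0.0, 1.0, 0.0, 1.0]
        with pytest.raises(ValueError, match="singular"):
            fit_ols(df, ModelSpec("y", ["x", "x2"]))
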