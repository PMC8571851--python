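"""Ordered logistic regression with free cutpoints, plus OLS and diagnostics.

Model.  An observed ordinal outcome with categories ``1..K`` arises from a
continuous latent variable ``y* = X b + e`` with standard-logistic error
``e`` cut at thresholds ``r_1 < ... < r_{K-1}``:

    P(y = k | x) = F(r_k - x'b) - F(r_{k-1} - x'b),   F(z) = 1/(1+exp(-z))

with ``r_0 = -inf`` and ``r_K = +inf``.  Identification is by *no intercept,
free cutpoints* (the cutpoints carry location), the convention of Stata's
``ologit``, so coefficients are comparable across refits.

Estimation maximizes the multinomial log-likelihood with analytic gradients:
an L-BFGS pass in an unconstrained parameterization (first cutpoint plus log
spacings) followed by damped Newton polishing until the infinity-norm of the
score is at most ``tol`` (default 1e-6).  Standard errors come from the
inverse observed information, or from the Huber-White sandwich
``H^{-1} (S'S) H^{-1}`` when ``robust_se`` is set (no clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .exceptions import ConfigError, ConvergenceError, SeparationError

__all__ = [
    "ModelSpec",
    "OrdinalFit",
    "OLSFit",
    "fit_ordered_logit",
    "predict_probs",
    "pseudo_r2",
    "odds_ratio",
    "vif_tolerance",
    "fit_ols",
]

_BETA_DIVERGED = 30.0  # |beta| beyond this is treated as separation


@dataclass
class ModelSpec:
    """What to regress on what.

    ``fixed_effect`` (e.g. the province column) enters as indicator
    contrasts with the first level as reference.
    """

    outcome: str
    predictors: list[str]
    fixed_effect: str | None = None
    robust_se: bool = False

    def __post_init__(self):
        if self.outcome in self.predictors:
            raise ConfigError(f"outcome '{self.outcome}' also listed among predictors")
        if self.fixed_effect is not None and self.fixed_effect in self.predictors:
            raise ConfigError(
                f"fixed_effect '{self.fixed_effect}' also listed among predictors"
            )
        if len(set(self.predictors)) != len(self.predictors):
            raise ConfigError("duplicate predictor names")


@dataclass
class OrdinalFit:
    """A fitted ordered-logit model."""

    coefficients: dict
    cutpoints: np.ndarray
    vcov: pd.DataFrame
    se: pd.Series
    log_likelihood: float
    null_log_likelihood: float
    n_obs: int
    outcome: str
    outcome_categories: np.ndarray
    predictor_names: list[str]
    fixed_effect: str | None = None
    fe_columns: list[str] = field(default_factory=list)
    robust_se: bool = False
    n_iter: int = 0
    grad_norm: float = np.nan

    @property
    def params(self) -> np.ndarray:
        return np.concatenate(
            [[self.coefficients[k] for k in self.predictor_names], self.cutpoints]
        )

    @property
    def odds_ratios(self) -> dict:
        return {k: float(np.exp(v)) for k, v in self.coefficients.items()}

    @property
    def pseudo_r2(self) -> float:
        return pseudo_r2(self)

    @property
    def zvalues(self) -> pd.Series:
        names = self.predictor_names + [f"cut_{j+1}" for j in range(len(self.cutpoints))]
        return pd.Series(self.params / self.se.to_numpy(), index=names)

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table (predictors only) with OR, SE and z."""
        rows = []
        for j, name in enumerate(self.predictor_names):
            b = self.coefficients[name]
            s = float(self.se.iloc[j])
            rows.append(
                {"term": name, "coef": b, "odds_ratio": float(np.exp(b)),
                 "std_err": s, "z": b / s}
            )
        return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# likelihood core


def _bounds(y: np.ndarray, cuts: np.ndarray):
    upper = np.append(cuts, np.inf)[y]
    lower = np.append(-np.inf, cuts)[y]
    return lower, upper


def _loglike_terms(eta, y, cuts):
    lower, upper = _bounds(y, cuts)
    zu = upper - eta
    zl = lower - eta
    with np.errstate(over="ignore", invalid="ignore"):
        # log[F(zu) - F(zl)] in a cancellation-free form
        gap = zl - zu  # <= 0; -inf at the bottom category
        ll = log_expit(zu) + log_expit(-zl) + np.log(-np.expm1(gap))
    return ll, zl, zu


def _nll_grad(theta_bt, X, y, K):
    """Negative log-likelihood and gradient in (beta, cutpoints) space."""
    p = X.shape[1]
    beta, cuts = theta_bt[:p], theta_bt[p:]
    eta = X @ beta if p else np.zeros(len(y))
    ll, zl, zu = _loglike_terms(eta, y, cuts)
    total = ll.sum()
    if not np.isfinite(total):
        return np.inf, np.zeros_like(theta_bt)
    with np.errstate(over="ignore", invalid="ignore"):
        Fu, Fl = expit(zu), expit(zl)
        fu = Fu * (1.0 - Fu)
        fl = Fl * (1.0 - Fl)
        prob = np.exp(ll)
        w_eta = (fl - fu) / prob  # d ll / d eta
        gu = fu / prob
        gl = fl / prob
    g_beta = X.T @ w_eta if p else np.empty(0)
    g_cut = np.zeros(K - 1)
    has_upper = y <= K - 2
    has_lower = y >= 1
    np.add.at(g_cut, y[has_upper], gu[has_upper])
    np.add.at(g_cut, y[has_lower] - 1, -gl[has_lower])
    return -total, -np.concatenate([g_beta, g_cut])


def _score_obs(theta_bt, X, y, K):
    """Per-observation score contributions over (beta, cutpoints)."""
    p = X.shape[1]
    beta, cuts = theta_bt[:p], theta_bt[p:]
    eta = X @ beta if p else np.zeros(len(y))
    ll, zl, zu = _loglike_terms(eta, y, cuts)
    Fu, Fl = expit(zu), expit(zl)
    fu = Fu * (1.0 - Fu)
    fl = Fl * (1.0 - Fl)
    prob = np.exp(ll)
    n = len(y)
    S = np.zeros((n, p + K - 1))
    if p:
        S[:, :p] = X * ((fl - fu) / prob)[:, None]
    rows = np.arange(n)
    has_upper = y <= K - 2
    has_lower = y >= 1
    S[rows[has_upper], p + y[has_upper]] += (fu / prob)[has_upper]
    S[rows[has_lower], p + y[has_lower] - 1] -= (fl / prob)[has_lower]
    return S


def _num_hessian(theta_bt, X, y, K):
    """Central finite differences of the analytic gradient."""
    m = theta_bt.size
    H = np.empty((m, m))
    h = 1e-5 * np.maximum(1.0, np.abs(theta_bt))
    for j in range(m):
        tp = theta_bt.copy()
        tm = theta_bt.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        _, gp = _nll_grad(tp, X, y, K)
        _, gm = _nll_grad(tm, X, y, K)
        H[:, j] = (gp - gm) / (2 * h[j])
    return 0.5 * (H + H.T)


def _pack_transformed(beta, cuts):
    if len(cuts) == 1:
        return np.concatenate([beta, cuts])
    return np.concatenate([beta, [cuts[0]], np.log(np.diff(cuts))])


def _unpack_transformed(theta, p, K):
    beta = theta[:p]
    if K == 2:
        cuts = theta[p:p + 1].copy()
    else:
        cuts = np.concatenate([[theta[p]], np.exp(theta[p + 1:])]).cumsum()
    return beta, cuts


def _nll_grad_transformed(theta, X, y, K):
    p = X.shape[1]
    beta, cuts = _unpack_transformed(theta, p, K)
    f, g = _nll_grad(np.concatenate([beta, cuts]), X, y, K)
    if not np.isfinite(f):
        return f, np.zeros_like(theta)
    g_beta, g_cut = g[:p], g[p:]
    out = np.empty_like(theta)
    out[:p] = g_beta
    out[p] = g_cut.sum()
    if K > 2:
        # d cut_j / d alpha_m = exp(alpha_m) for j >= m
        rev = np.cumsum(g_cut[::-1])[::-1]
        out[p + 1:] = np.exp(theta[p + 1:]) * rev[1:]
    return f, out


def _fit_core(y, X, tol=1e-6, maxiter=500):
    """Maximum-likelihood fit; returns params, vcov pieces and diagnostics."""
    n, p = X.shape
    K = int(y.max()) + 1
    counts = np.bincount(y, minlength=K).astype(float)
    cum = np.cumsum(counts)[:-1] / n
    cuts0 = np.log(cum / (1.0 - cum))  # empirical logits of cumulative freqs
    theta0 = _pack_transformed(np.zeros(p), cuts0)

    res = minimize(
        _nll_grad_transformed, theta0, args=(X, y, K), jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9},
    )
    beta, cuts = _unpack_transformed(res.x, p, K)
    theta = np.concatenate([beta, cuts])

    # Newton polish in (beta, cutpoints) space to the required score norm
    trace = []
    nll, g = _nll_grad(theta, X, y, K)
    for it in range(50):
        if p and np.abs(theta[:p]).max() > _BETA_DIVERGED:
            raise SeparationError(
                "coefficient diverged (|beta| > "
                f"{_BETA_DIVERGED:g}); data are (quasi-)separated"
            )
        gnorm = float(np.abs(g).max())
        trace.append(gnorm)
        if gnorm <= tol:
            break
        H = _num_hessian(theta, X, y, K)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        lam = 1.0
        # descent test allows rounding noise at the likelihood's own scale
        f_slack = 1e-10 * (1.0 + abs(nll))
        for _ in range(40):
            cand = theta - lam * step
            c_cuts = cand[p:]
            f_new, g_new = _nll_grad(cand, X, y, K)
            if (np.all(np.diff(c_cuts) > 0) or K == 2) and np.isfinite(f_new):
                if f_new <= nll + f_slack or np.abs(g_new).max() < gnorm:
                    break
            lam *= 0.5
        else:
            raise ConvergenceError(
                f"line search failed at iteration {it} (|grad|={gnorm:.3g})",
                trace,
            )
        theta, nll, g = cand, f_new, g_new
    else:
        raise ConvergenceError(
            f"score norm {trace[-1]:.3g} > tol {tol} after {len(trace)} "
            "Newton iterations",
            trace,
        )

    beta, cuts = theta[:p], theta[p:]
    if p and np.abs(beta).max() > _BETA_DIVERGED:
        raise SeparationError(
            "coefficient diverged (|beta| > "
            f"{_BETA_DIVERGED:g}); data are (quasi-)separated"
        )
    H = _num_hessian(theta, X, y, K)
    vcov = np.linalg.pinv(H)
    S = _score_obs(theta, X, y, K)
    vcov_robust = vcov @ (S.T @ S) @ vcov
    ll_null = float(np.sum(counts[counts > 0] * np.log(counts[counts > 0] / n)))
    return {
        "beta": beta,
        "cuts": cuts,
        "loglike": -nll,
        "null_loglike": ll_null,
        "vcov": vcov,
        "vcov_robust": vcov_robust,
        "n_iter": len(trace),
        "grad_norm": trace[-1] if trace else 0.0,
        "K": K,
    }


# ---------------------------------------------------------------------------
# public interface


def _build_design(table: pd.DataFrame, spec: ModelSpec):
    for col in spec.predictors:
        if col not in table.columns:
            raise KeyError(f"predictor column '{col}' not in table")
    X = table[spec.predictors].astype(float)
    fe_cols: list[str] = []
    if spec.fixed_effect is not None:
        if spec.fixed_effect not in table.columns:
            raise KeyError(f"fixed-effect column '{spec.fixed_effect}' not in table")
        dummies = pd.get_dummies(
            table[spec.fixed_effect], prefix=spec.fixed_effect, drop_first=True,
            dtype=float,
        )
        fe_cols = list(dummies.columns)
        X = pd.concat([X, dummies], axis=1)
    return X, fe_cols


def fit_ordered_logit(
    table: pd.DataFrame, spec: ModelSpec, tol: float = 1e-6, maxiter: int = 500
) -> OrdinalFit:
    """Fit the ordered-logit model defined by ``spec`` on ``table``."""
    if spec.outcome not in table.columns:
        raise KeyError(f"outcome column '{spec.outcome}' not in table")
    Xdf, fe_cols = _build_design(table, spec)
    names = list(Xdf.columns)
    X = Xdf.to_numpy(dtype=float)

    zero_var = [c for c in spec.predictors if table[c].nunique() <= 1]
    if zero_var:
        raise ValueError(f"zero-variance predictor(s): {zero_var}")

    cats, y = np.unique(np.asarray(table[spec.outcome]), return_inverse=True)
    K = len(cats)
    if K < 2:
        raise ValueError(f"outcome '{spec.outcome}' has a single observed category")
    n = len(y)
    if n <= X.shape[1] + K - 1:
        raise ValueError("fewer observations than parameters")

    core = _fit_core(y, X, tol=tol, maxiter=maxiter)
    param_names = names + [f"cut_{j+1}" for j in range(K - 1)]
    V = core["vcov_robust"] if spec.robust_se else core["vcov"]
    vcov = pd.DataFrame(V, index=param_names, columns=param_names)
    se = pd.Series(np.sqrt(np.clip(np.diag(V), 0, None)), index=param_names)
    return OrdinalFit(
        coefficients=dict(zip(names, core["beta"])),
        cutpoints=core["cuts"],
        vcov=vcov,
        se=se,
        log_likelihood=core["loglike"],
        null_log_likelihood=core["null_loglike"],
        n_obs=n,
        outcome=spec.outcome,
        outcome_categories=cats,
        predictor_names=names,
        fixed_effect=spec.fixed_effect,
        fe_columns=fe_cols,
        robust_se=spec.robust_se,
        n_iter=core["n_iter"],
        grad_norm=core["grad_norm"],
    )


def predict_probs(fit: OrdinalFit, rows: pd.DataFrame) -> np.ndarray:
    """Category probabilities ``P(y = k | x)`` for each row (rows sum to 1)."""
    base = [c for c in fit.predictor_names if c not in fit.fe_columns]
    missing = [c for c in base if c not in rows.columns]
    if missing:
        raise KeyError(f"missing predictor column(s): {missing}")
    X = rows[base].astype(float)
    if fit.fixed_effect is not None:
        if fit.fixed_effect not in rows.columns:
            raise KeyError(f"missing fixed-effect column '{fit.fixed_effect}'")
        dummies = pd.get_dummies(
            rows[fit.fixed_effect], prefix=fit.fixed_effect, dtype=float
        )
        dummies = dummies.reindex(columns=fit.fe_columns, fill_value=0.0)
        X = pd.concat([X, dummies], axis=1)
    beta = np.array([fit.coefficients[c] for c in fit.predictor_names])
    eta = X[fit.predictor_names].to_numpy(dtype=float) @ beta
    cdf = expit(fit.cutpoints[None, :] - eta[:, None])
    cdf = np.hstack([np.zeros((len(eta), 1)), cdf, np.ones((len(eta), 1))])
    return np.diff(cdf, axis=1)


def pseudo_r2(fit: OrdinalFit) -> float:
    """McFadden's pseudo-R²: ``1 - ll_full / ll_null``."""
    if fit.null_log_likelihood == 0.0:
        raise ZeroDivisionError("null log-likelihood is zero")
    return 1.0 - fit.log_likelihood / fit.null_log_likelihood


def odds_ratio(coefficient: float) -> float:
    """Odds ratio ``exp(b)`` for a latent-scale coefficient."""
    return float(np.exp(coefficient))


def vif_tolerance(table: pd.DataFrame, predictors: list[str]) -> dict:
    """Variance-inflation factor and tolerance per predictor.

    ``vif_k = 1/(1 - R²_k)`` from regressing predictor ``k`` on the others
    (with intercept); ``tolerance = 1/vif``.  Exact collinearity is reported
    as ``vif = inf`` (tolerance 0) rather than raising.
    """
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors for collinearity diagnostics")
    Z = table[list(predictors)].astype(float)
    for c in predictors:
        if Z[c].std(ddof=0) == 0:
            raise ValueError(f"predictor '{c}' has zero variance")
    out = {}
    for c in predictors:
        others = [o for o in predictors if o != c]
        exog = sm.add_constant(Z[others].to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = sm.OLS(Z[c].to_numpy(), exog).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            out[c] = {"vif": np.inf, "tolerance": 0.0, "collinear": True}
        else:
            vif = 1.0 / (1.0 - r2)
            out[c] = {"vif": float(vif), "tolerance": float(1.0 / vif),
                      "collinear": False}
    return out


@dataclass
class OLSFit:
    """Least-squares fit used by the continuous-outcome robustness variant."""

    coefficients: dict
    se: dict
    r_squared: float
    n_obs: int
    outcome: str

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients)


def fit_ols(table: pd.DataFrame, spec: ModelSpec) -> OLSFit:
    """OLS with the same design conventions as the ordered-logit fit."""
    if spec.outcome not in table.columns:
        raise KeyError(f"outcome column '{spec.outcome}' not in table")
    Xdf, _ = _build_design(table, spec)
    X = sm.add_constant(Xdf.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    y = table[spec.outcome].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit(cov_type="HC1" if spec.robust_se else "nonrobust")
    names = ["const"] + list(Xdf.columns)
    return OLSFit(
        coefficients=dict(zip(names, res.params)),
        se=dict(zip(names, res.bse)),
        r_squared=float(res.rsquared),
        n_obs=int(res.nobs),
        outcome=spec.outcome,
    )
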