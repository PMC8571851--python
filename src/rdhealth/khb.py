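"""KHB decomposition of exposure effects into direct and mediated components.

In nonlinear probability models (here: ordered logit) the coefficients of
nested models are not directly comparable because adding a mediator rescales
the latent variable.  The KHB (Karlson-Holm-Breen) device restores
comparability: the *reduced* model replaces the mediator with its residual
from a linear regression of the mediator on the exposure and covariates, so
the reduced and full models condition on the same information and share one
latent scale.  Then

    TE = exposure coefficient of the reduced fit   (total effect)
    DE = exposure coefficient of the full fit      (direct effect)
    IE = TE - DE                                   (mediated, by construction)

Because the reduced and full designs span the same column space, IE equals
the product ``b*c`` of the mediator-equation slope and the full-model
mediator coefficient — exactly, also in the logit family.  Mediators are
decomposed one at a time; uncertainty comes from a row-resampling bootstrap
(default) or a delta-method (Sobel) approximation for the indirect term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .ordinal import ModelSpec, OLSFit, fit_ordered_logit, fit_ols

__all__ = ["KHBResult", "khb_decompose", "khb_se", "mediation_table"]


@dataclass
class KHBResult:
    """Total/direct/indirect effect of an exposure through one mediator."""

    outcome: str
    exposure: str
    mediator: str
    total_effect: float
    direct_effect: float
    indirect_effect: float = None  # always TE - DE; filled in __post_init__
    se_te: float = np.nan
    se_de: float = np.nan
    se_ie: float = np.nan
    se_method: str = "none"
    n_obs: int = 0

    def __post_init__(self):
        # exact ledger identity, never estimated separately
        self.indirect_effect = self.total_effect - self.direct_effect

    @property
    def or_te(self) -> float:
        return float(np.exp(self.total_effect))

    @property
    def or_de(self) -> float:
        return float(np.exp(self.direct_effect))

    @property
    def or_ie(self) -> float:
        return float(np.exp(self.indirect_effect))

    @property
    def z_te(self) -> float:
        return self.total_effect / self.se_te

    @property
    def z_de(self) -> float:
        return self.direct_effect / self.se_de

    @property
    def z_ie(self) -> float:
        return self.indirect_effect / self.se_ie

    @property
    def mediation_pct(self) -> float:
        """Share of the total effect flowing through the mediator, in %."""
        return 100.0 * self.indirect_effect / self.total_effect


def _decompose_once(table, outcome, exposure, mediator, covariates,
                    fixed_effect, family):
    """One decomposition pass; returns (result, b, c, se_b, se_c)."""
    covariates = list(covariates)
    # mediator equation: m ~ exposure + covariates (+ FE), by OLS
    med_spec = ModelSpec(outcome=mediator, predictors=[exposure] + covariates,
                         fixed_effect=fixed_effect)
    med_fit: OLSFit = fit_ols(table, med_spec)
    b = med_fit.coefficients[exposure]
    se_b = med_fit.se[exposure]
    # residualized mediator
    exog_cols = [exposure] + covariates
    X = table[exog_cols].astype(float)
    if fixed_effect is not None:
        X = pd.concat(
            [X, pd.get_dummies(table[fixed_effect], prefix=fixed_effect,
                               drop_first=True, dtype=float)], axis=1)
    X = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    m = table[mediator].to_numpy(dtype=float)
    resid = m - X @ np.linalg.lstsq(X, m, rcond=None)[0]

    work = table.copy()
    work["_mediator_resid"] = resid
    reduced_spec = ModelSpec(
        outcome=outcome, predictors=[exposure, "_mediator_resid"] + covariates,
        fixed_effect=fixed_effect, robust_se=True)
    full_spec = ModelSpec(
        outcome=outcome, predictors=[exposure, mediator] + covariates,
        fixed_effect=fixed_effect, robust_se=True)
    if family == "ordered_logit":
        fitter = fit_ordered_logit
        get = lambda fit, name: (fit.coefficients[name], float(fit.se[name]))
    elif family == "ols":
        fitter = fit_ols
        get = lambda fit, name: (fit.coefficients[name], fit.se[name])
    else:
        raise ValueError(f"unknown family '{family}'")
    try:
        reduced = fitter(work, reduced_spec)
    except Exception as exc:  # noqa: BLE001 - annotate which fit failed
        raise RuntimeError(f"reduced (total-effect) model failed: {exc}") from exc
    try:
        full = fitter(work, full_spec)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"full (direct-effect) model failed: {exc}") from exc

    te, se_te = get(reduced, exposure)
    de, se_de = get(full, exposure)
    c, se_c = get(full, mediator)
    result = KHBResult(
        outcome=outcome, exposure=exposure, mediator=mediator,
        total_effect=te, direct_effect=de,
        se_te=se_te, se_de=se_de, n_obs=len(table))
    return result, b, c, se_b, se_c


def khb_decompose(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    mediator: str,
    covariates: list[str] | None = None,
    fixed_effect: str | None = None,
    family: str = "ordered_logit",
) -> KHBResult:
    """Decompose the exposure effect on ``outcome`` through one ``mediator``.

    Returns a :class:`KHBResult` with delta-method (Sobel) uncertainty for
    the indirect term; call :func:`khb_se` for bootstrap standard errors.
    """
    if table[mediator].nunique() <= 1:
        raise ValueError(f"mediator '{mediator}' is constant")
    covariates = list(covariates or [])
    result, b, c, se_b, se_c = _decompose_once(
        table, outcome, exposure, mediator, covariates, fixed_effect, family)
    # Delta-method variance of IE = b*c, Goodman's unbiased product form;
    # falls back to the plug-in (Sobel) form if the correction overshoots.
    var_ie = c**2 * se_b**2 + b**2 * se_c**2 - se_b**2 * se_c**2
    if var_ie <= 0:
        var_ie = c**2 * se_b**2 + b**2 * se_c**2
    result.se_ie = float(np.sqrt(var_ie))
    result.se_method = "delta"
    result._context = dict(
        table=table, outcome=outcome, exposure=exposure, mediator=mediator,
        covariates=covariates, fixed_effect=fixed_effect, family=family)
    return result


def khb_se(
    result: KHBResult,
    method: str = "bootstrap",
    n_boot: int = 200,
    seed: int = 0,
) -> KHBResult:
    """Standard errors for TE/DE/IE by bootstrap (default) or delta method.

    The bootstrap resamples rows with replacement and refits the whole
    decomposition; deterministic given ``seed``.
    """
    ctx = getattr(result, "_context", None)
    if ctx is None:
        raise ValueError("result carries no refitting context")
    if method == "delta":
        return result  # filled during khb_decompose
    if method != "bootstrap":
        raise ValueError(f"unknown SE method '{method}'")
    if n_boot < 50:
        raise ValueError("n_boot must be at least 50")
    rng = np.random.default_rng(seed)
    table = ctx["table"]
    n = len(table)
    draws = np.empty((n_boot, 3))
    for r in range(n_boot):
        idx = rng.integers(0, n, n)
        res_r, *_ = _decompose_once(
            table.iloc[idx].reset_index(drop=True), ctx["outcome"],
            ctx["exposure"], ctx["mediator"], ctx["covariates"],
            ctx["fixed_effect"], ctx["family"])
        draws[r] = (res_r.total_effect, res_r.direct_effect,
                    res_r.indirect_effect)
    se = draws.std(axis=0, ddof=1)
    out = replace(result, se_te=float(se[0]), se_de=float(se[1]),
                  se_ie=float(se[2]), se_method=f"bootstrap({n_boot})")
    out._context = ctx
    return out


def mediation_table(results: list[KHBResult]) -> pd.DataFrame:
    """Report shaped like the published mediation table.

    One TE/DE/IE row triple per (outcome, mediator) with coefficient, odds
    ratio (``exp`` of the coefficient), standard error, z, two-sided normal
    p-value and the mediation percentage ``100 * IE / TE``.
    """
    if not results:
        raise ValueError("empty result list")
    rows = []
    for res in results:
        triples = [
            ("TE", res.total_effect, res.se_te),
            ("DE", res.direct_effect, res.se_de),
            ("IE", res.indirect_effect, res.se_ie),
        ]
        for label, coef, se in triples:
            z = coef / se if se and np.isfinite(se) and se > 0 else np.nan
            rows.append({
                "outcome": res.outcome,
                "mediator": res.mediator,
                "effect": label,
                "coef": coef,
                "odds_ratio": float(np.exp(coef)),
                "std_err": se,
                "z": z,
                "p_value": float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                "mediation_pct": round(res.mediation_pct, 2) if label == "TE" else np.nan,
            })
    return pd.DataFrame(rows)
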