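"""Robustness battery and subgroup-heterogeneity driver.

Variants mirror the checks an analyst runs to show the deprivation -> health
association is not an artifact of one set of choices:

- ``swap_outcome_selfrated``: refit with the self-rated health column.
- ``swap_index_yitzhaki_log``: replace the Kakwani exposure by the Yitzhaki
  index computed on log income (scale-robust variant).
- ``swap_index_podder``: replace it by the Podder (log-ratio) index.
- ``winsorize_1pct``: winsorize (or trim) the income tails at 1%, recompute
  the deprivation index, refit.
- ``ols_continuous``: treat the ordinal outcome as numeric and fit OLS.

Subgroup runs split by gender / household registration / region and, by
default, re-reference the deprivation index within each subgroup (each
subgroup's own income vector becomes the comparison set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy.stats.mstats import winsorize as _mstats_winsorize

from .deprivation import kakwani, podder, yitzhaki
from .ordinal import ModelSpec, fit_ols, fit_ordered_logit

__all__ = [
    "VARIANTS",
    "RobustnessPlan",
    "SubgroupPlan",
    "winsorize",
    "run_robustness",
    "run_subgroups",
]

VARIANTS = (
    "swap_outcome_selfrated",
    "swap_index_yitzhaki_log",
    "swap_index_podder",
    "winsorize_1pct",
    "ols_continuous",
)


@dataclass
class RobustnessPlan:
    variants: list[str]
    base_spec: ModelSpec
    winsor_fraction: float = 0.01
    winsor_mode: str = "winsor"  # or "trim"
    exposure: str = "kakwani"
    income_col: str = "income_pc"
    selfrated_col: str = "srhealth"

    def __post_init__(self):
        if not self.variants:
            raise ValueError("variant list is empty")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variant(s): {sorted(unknown)}")
        if not 0 < self.winsor_fraction < 0.5:
            raise ValueError("winsor_fraction must be in (0, 0.5)")
        if self.winsor_mode not in ("winsor", "trim"):
            raise ValueError("winsor_mode must be 'winsor' or 'trim'")


@dataclass
class SubgroupPlan:
    dimension: str  # gender | urban | region
    re_reference_deprivation: bool = True

    def __post_init__(self):
        if self.dimension not in ("gender", "urban", "region"):
            raise ValueError("dimension must be one of gender, urban, region")


def winsorize(values, fraction: float) -> np.ndarray:
    """Order-statistic winsorization of both tails.

    The ``floor(n * fraction)`` smallest values are replaced by the next
    order statistic, symmetrically at the top; length is preserved and the
    operation is idempotent.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    x = np.asarray(values, dtype=float)
    return np.asarray(_mstats_winsorize(x, limits=(fraction, fraction)))


def _trim_mask(values, fraction: float) -> np.ndarray:
    """Keep-rows mask dropping the floor(n*fraction) extreme values per tail."""
    x = np.asarray(values, dtype=float)
    k = int(np.floor(fraction * x.size))
    if k == 0:
        return np.ones(x.size, dtype=bool)
    order = np.argsort(x, kind="stable")
    mask = np.ones(x.size, dtype=bool)
    mask[order[:k]] = False
    mask[order[-k:]] = False
    return mask


@dataclass
class VariantResult:
    variant: str
    outcome: str
    n_obs: int
    estimator: str
    coefficients: dict  # term -> (estimate, se)
    fit_stat: float  # pseudo-R2 (ordered logit) or R2 (OLS)


def _summarize_ordinal(fit, terms):
    return {t: (fit.coefficients[t], float(fit.se[t])) for t in terms}


def _require(table, col, variant):
    if col not in table.columns:
        raise KeyError(f"variant '{variant}' needs missing column '{col}'")


def run_robustness(table: pd.DataFrame, plan: RobustnessPlan) -> dict:
    """Run each requested variant; returns ``{variant: VariantResult}``."""
    spec = plan.base_spec
    terms = list(spec.predictors)
    out: dict[str, VariantResult] = {}
    for variant in plan.variants:
        work = table
        vspec = spec
        estimator = "ordered_logit"
        if variant == "swap_outcome_selfrated":
            _require(table, plan.selfrated_col, variant)
            vspec = dc_replace(spec, outcome=plan.selfrated_col)
        elif variant in ("swap_index_yitzhaki_log", "swap_index_podder"):
            _require(table, plan.income_col, variant)
            _require(table, plan.exposure, variant)
            income = table[plan.income_col].to_numpy(dtype=float)
            if variant == "swap_index_yitzhaki_log":
                scores = yitzhaki(np.log(income)).scores
            else:
                scores = podder(income).scores
            work = table.copy()
            work[plan.exposure] = scores
        elif variant == "winsorize_1pct":
            _require(table, plan.income_col, variant)
            _require(table, plan.exposure, variant)
            work = table.copy()
            if plan.winsor_mode == "winsor":
                work[plan.income_col] = winsorize(
                    work[plan.income_col].to_numpy(), plan.winsor_fraction)
            else:
                keep = _trim_mask(
                    work[plan.income_col].to_numpy(), plan.winsor_fraction)
                work = work.loc[keep].reset_index(drop=True)
            work[plan.exposure] = kakwani(
                work[plan.income_col].to_numpy()).scores
        elif variant == "ols_continuous":
            estimator = "ols"

        if estimator == "ols":
            fit = fit_ols(work, vspec)
            coeffs = {t: (fit.coefficients[t], fit.se[t]) for t in terms}
            out[variant] = VariantResult(
                variant, vspec.outcome, fit.n_obs, "ols", coeffs,
                fit.r_squared)
        else:
            fit = fit_ordered_logit(work, vspec)
            out[variant] = VariantResult(
                variant, vspec.outcome, fit.n_obs, "ordered_logit",
                _summarize_ordinal(fit, terms), fit.pseudo_r2)
    return out


@dataclass
class SubgroupResult:
    dimension: str
    fits: dict = field(default_factory=dict)  # level -> OrdinalFit
    skipped: dict = field(default_factory=dict)  # level -> reason

    @property
    def n_total(self) -> int:
        return sum(f.n_obs for f in self.fits.values())


def run_subgroups(
    table: pd.DataFrame,
    plan: SubgroupPlan,
    spec: ModelSpec,
    exposure: str = "kakwani",
    income_col: str = "income_pc",
) -> SubgroupResult:
    """Refit the model within each level of ``plan.dimension``.

    With ``re_reference_deprivation`` the Kakwani exposure is recomputed on
    each subgroup's own income vector before fitting (the comparison group
    changes with the stratum).  Subgroups whose outcome collapses to one
    category are skipped with a warning.
    """
    if plan.dimension not in table.columns:
        raise KeyError(f"dimension column '{plan.dimension}' not in table")
    result = SubgroupResult(dimension=plan.dimension)
    for level, sub in table.groupby(plan.dimension, sort=True, observed=True):
        sub = sub.reset_index(drop=True)
        if sub[spec.outcome].nunique() < 2:
            msg = f"subgroup {plan.dimension}={level!r} has one outcome category"
            warnings.warn(msg)
            result.skipped[level] = msg
            continue
        if plan.re_reference_deprivation:
            sub = sub.copy()
            sub[exposure] = kakwani(
                sub[income_col].to_numpy(),
                reference_group=f"{plan.dimension}={level}").scores
        result.fits[level] = fit_ordered_logit(sub, spec)
    return result
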