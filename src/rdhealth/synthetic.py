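"""Synthetic survey microdata with the generative structure the analysis assumes.

The generator emulates a CFPS-like cross-section of adult respondents: a
log-normal household per-capita income, an individual Kakwani deprivation
score computed *within the generated sample*, five social-capital mediators
eroded by deprivation, and two ordinal health outcomes (mental health 1-5,
physical health 1-4) produced by a latent-variable ordered-logit mechanism:

    m_k      = mean_k + b_k * (KI - mean(KI)) + Gaussian noise
    health*  = a * (KI - mean(KI)) + sum_k c_k * (m_k - mean_k)
               + gamma' (x - mean(x)) + prov + logistic noise
    outcome  = 1 + #{cutpoints below health*}

Centring keeps the latent scale anchored at zero so the default cutpoints
directly set the marginal category frequencies.  Default parameter values
reproduce the survey's published marginal moments (urban share 0.493, mean
age 47.8, income Gini near 0.51, mental-health mean/SD near 4.24/0.82) and
the direction claims the analysis tests: deprivation harms health (a < 0),
deprivation erodes social capital (b < 0), cognitive social capital helps
health (c > 0).

A self-rated health column (``srhealth``, 1-5) is generated from the same
latent mechanism with independent noise, for the outcome-swap robustness
variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .deprivation import kakwani
from .exceptions import ConfigError

__all__ = ["MEDIATORS", "COLUMN_ORDER", "SyntheticConfig", "generate", "marginal_report"]

MEDIATORS = ("trust", "fair", "support", "relations", "jiegousc")

#: target marginal mean/SD and admissible range per mediator
_MEDIATOR_MOMENTS = {
    "trust": (5.575, 1.343, (0.0, 10.0), False),
    "fair": (3.309, 1.540, (1.0, 8.0), False),
    "support": (4.220, 3.983, (0.0, None), False),
    "relations": (7.109, 1.981, (0.0, 10.0), True),  # ordinal 0-10
    "jiegousc": (7.277, 2.437, (0.0, None), False),
}

_DEFAULT_COVARIATE_EFFECTS = {
    "urban": 0.11, "gender": 0.48, "age": -0.004, "marriage": 0.28,
    "education": 0.03, "employ": 0.05, "insurance": 0.11, "family": 0.08,
    "status": 0.05, "exercise": 0.03, "smoke": -0.08, "drink": 0.07,
    "break": 0.01, "satisfaction": 0.08, "care": 0.12,
}

COLUMN_ORDER = [
    "income_pc", "mh", "ph", "srhealth",
    "trust", "fair", "support", "relations", "jiegousc",
    "urban", "gender", "age", "marriage", "education",
    "employ", "insurance", "family", "status",
    "exercise", "smoke", "drink", "break",
    "satisfaction", "care", "province", "region",
]


@dataclass
class SyntheticConfig:
    """All generator parameters; defaults are the study conditions."""

    n_respondents: int = 22751
    n_provinces: int = 31
    income_log_mean: float = 9.8
    income_log_sd: float = 0.972  # implies a population income Gini near 0.508
    path_a: float = -0.9  # deprivation -> latent health, per unit Kakwani
    path_b: tuple = (-1.5, -1.5, -2.0, -1.5, -2.0)  # deprivation -> mediator
    path_c: tuple = (0.15, 0.10, 0.02, 0.03, 0.02)  # mediator -> latent health
    covariate_effects: dict = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS)
    )
    province_effect_sd: float = 0.3
    mh_cutpoints: tuple = (-4.4, -3.2, -1.85, 0.05)
    ph_cutpoints: tuple = (-3.25, -1.9, -0.3)
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_respondents, (int, np.integer)) and self.n_respondents >= 2):
            raise ConfigError("n_respondents must be an integer >= 2")
        if not (isinstance(self.n_provinces, (int, np.integer)) and self.n_provinces >= 1):
            raise ConfigError("n_provinces must be a positive integer")
        if not self.income_log_sd > 0:
            raise ConfigError("income_log_sd must be > 0")
        if len(self.path_b) != len(MEDIATORS):
            raise ConfigError(f"path_b must have {len(MEDIATORS)} entries")
        if len(self.path_c) != len(MEDIATORS):
            raise ConfigError(f"path_c must have {len(MEDIATORS)} entries")
        if self.province_effect_sd < 0:
            raise ConfigError("province_effect_sd must be >= 0")
        if len(self.mh_cutpoints) != 4 or np.any(np.diff(self.mh_cutpoints) <= 0):
            raise ConfigError("mh_cutpoints must be 4 strictly increasing reals")
        if len(self.ph_cutpoints) != 3 or np.any(np.diff(self.ph_cutpoints) <= 0):
            raise ConfigError("ph_cutpoints must be 3 strictly increasing reals")
        unknown = set(self.covariate_effects) - set(_DEFAULT_COVARIATE_EFFECTS)
        if unknown:
            raise ConfigError(f"covariate_effects for unknown column(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["path_b"] = list(self.path_b)
        d["path_c"] = list(self.path_c)
        d["mh_cutpoints"] = list(self.mh_cutpoints)
        d["ph_cutpoints"] = list(self.ph_cutpoints)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        kwargs = dict(d)
        for key in ("path_b", "path_c", "mh_cutpoints", "ph_cutpoints"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _ordinal_choice(rng, probs, n, start=1):
    return rng.choice(np.arange(start, start + len(probs)), size=n, p=probs)


def _covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Covariates with marginals near the survey's published moments."""
    cov = pd.DataFrame(index=np.arange(n))
    cov["urban"] = (rng.random(n) < 0.493).astype(int)
    cov["gender"] = (rng.random(n) < 0.478).astype(int)
    cov["age"] = np.clip(rng.normal(47.8, 16.5, n), 20, 81).round(0)
    cov["marriage"] = (rng.random(n) < 0.825).astype(int)
    cov["education"] = np.clip(rng.normal(7.33, 5.3, n), 0, 22).round(0)
    cov["employ"] = (rng.random(n) < 0.777).astype(int)
    cov["insurance"] = (rng.random(n) < 0.916).astype(int)
    cov["family"] = np.clip(1 + rng.poisson(3.145, n), 1, 21)
    cov["status"] = _ordinal_choice(rng, [0.10, 0.20, 0.33, 0.24, 0.13], n)
    active = rng.random(n) < 0.55
    cov["exercise"] = np.where(active, rng.gamma(2.0, 2.27, n), 0.0).round(1)
    cov["smoke"] = (rng.random(n) < 0.299).astype(int)
    cov["drink"] = (rng.random(n) < 0.155).astype(int)
    cov["break"] = (rng.random(n) < 0.536).astype(int)
    cov["satisfaction"] = _ordinal_choice(rng, [0.02, 0.06, 0.32, 0.47, 0.13], n)
    cov["care"] = _ordinal_choice(rng, [0.02, 0.09, 0.37, 0.41, 0.11], n)
    return cov


def _regions(n_provinces: int) -> np.ndarray:
    """Deterministic province -> region map: ~45% east, ~25% central, rest west."""
    n_east = int(round(0.45 * n_provinces))
    n_central = int(round(0.25 * n_provinces))
    labels = np.array(["east"] * n_east + ["central"] * n_central
                      + ["west"] * (n_provinces - n_east - n_central))
    return labels


def generate(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one survey table; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_respondents)

    income = rng.lognormal(config.income_log_mean, config.income_log_sd, n)
    ki = kakwani(income).scores
    ki_c = ki - ki.mean()

    cov = _covariates(rng, n)
    gamma = np.zeros(n)
    for name, eff in config.covariate_effects.items():
        x = cov[name].to_numpy(dtype=float)
        gamma += eff * (x - x.mean())

    med = pd.DataFrame(index=cov.index)
    systematic = config.path_a * ki_c + gamma
    for k, name in enumerate(MEDIATORS):
        mean_k, sd_k, (lo, hi), is_ordinal = _MEDIATOR_MOMENTS[name]
        signal = config.path_b[k] * ki_c
        resid_sd = np.sqrt(max(sd_k**2 - np.var(signal), 0.04))
        m = mean_k + signal + rng.normal(0.0, resid_sd, n)
        m = np.clip(m, lo, hi if hi is not None else np.inf)
        if is_ordinal:
            m = np.round(m).astype(int)
        med[name] = m
        systematic = systematic + config.path_c[k] * (
            med[name].to_numpy(dtype=float) - mean_k
        )

    province = rng.integers(0, config.n_provinces, n)
    prov_eff = rng.normal(0.0, config.province_effect_sd, config.n_provinces)
    systematic = systematic + prov_eff[province]

    mh = 1 + np.searchsorted(
        config.mh_cutpoints, systematic + rng.logistic(0.0, 1.0, n)
    )
    ph = 1 + np.searchsorted(
        config.ph_cutpoints, systematic + rng.logistic(0.0, 1.0, n)
    )
    srhealth = 1 + np.searchsorted(
        config.mh_cutpoints, systematic + rng.logistic(0.0, 1.0, n)
    )

    table = pd.DataFrame({"income_pc": income, "mh": mh, "ph": ph,
                          "srhealth": srhealth})
    table = pd.concat([table, med, cov], axis=1)
    table["province"] = province
    table["region"] = _regions(config.n_provinces)[province]
    table = table[COLUMN_ORDER]
    assert not table.isna().any().any(), "generator must not emit missing values"
    return table


def marginal_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-column mean and SD (numeric columns), for eyeballing fidelity."""
    if len(table) == 0:
        raise ValueError("empty table")
    num = table.select_dtypes(include=[np.number])
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
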