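"""End-to-end pipeline: deprivation -> regression -> mediation -> robustness.

Stage order follows the analysis design: compute the individual deprivation
exposure, fit the ordered-logit health models, decompose mediation through
each social-capital channel, then run the robustness and subgroup batteries.
Every artifact is a text file (CSV/TSV/JSON) and a manifest records inputs,
seeds and row counts so a run is reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deprivation import group_deprivation
from .exceptions import ConfigError, PipelineError
from .io import read_survey_csv, write_table
from .khb import khb_decompose, khb_se, mediation_table
from .ordinal import ModelSpec, fit_ordered_logit
from .robustness import (RobustnessPlan, SubgroupPlan, VARIANTS,
                         run_robustness, run_subgroups)
from .synthetic import MEDIATORS, SyntheticConfig, generate

logger = logging.getLogger("rdhealth")

DEFAULT_COVARIATES = [
    "urban", "gender", "age", "marriage", "education", "employ", "insurance",
    "family", "status", "exercise", "smoke", "drink", "break",
    "satisfaction", "care",
]
STAGES = ("deprivation", "fit", "mediation", "robustness", "subgroups")


@dataclass
class PipelineConfig:
    """Everything one run needs; construct directly or via :meth:`from_dict`."""

    output_dir: str
    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    column_map: dict = field(default_factory=dict)
    stages: list[str] = field(default_factory=lambda: ["deprivation", "fit", "mediation"])
    income_col: str = "income_pc"
    outcomes: list[str] = field(default_factory=lambda: ["mh", "ph"])
    mediators: list[str] = field(default_factory=lambda: list(MEDIATORS))
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    fixed_effect: str | None = "province"
    se_method: str = "bootstrap"  # or "delta"
    n_boot: int = 200
    subgroup_dimensions: list[str] = field(default_factory=lambda: ["gender", "urban", "region"])
    robustness_variants: list[str] = field(default_factory=lambda: list(VARIANTS))
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synthetic" in d and d["synthetic"] is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        return cls(**d)

    def validate(self, table: pd.DataFrame | None = None) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigError("exactly one of input_path or synthetic must be set")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        if table is not None:
            needed = {self.income_col, *self.outcomes}
            needed.update(self.covariates)
            if "mediation" in self.stages:
                if not self.mediators:
                    raise ConfigError("mediation stage requested without mediators")
                needed.update(self.mediators)
            if self.fixed_effect:
                needed.add(self.fixed_effect)
            missing = sorted(needed - set(table.columns))
            if missing:
                raise ConfigError(f"table lacks required column(s): {missing}")
            downstream = set(self.stages) - {"deprivation"}
            if downstream and "deprivation" not in self.stages \
                    and "kakwani" not in table.columns:
                raise ConfigError(
                    "stages beyond 'deprivation' need a 'kakwani' column or "
                    "the deprivation stage first"
                )


def _fit_to_dict(fit) -> dict:
    return {
        "outcome": fit.outcome,
        "n_obs": fit.n_obs,
        "coefficients": {k: float(v) for k, v in fit.coefficients.items()},
        "odds_ratios": fit.odds_ratios,
        "std_errors": {k: float(fit.se[k]) for k in fit.predictor_names},
        "cutpoints": [float(c) for c in fit.cutpoints],
        "log_likelihood": fit.log_likelihood,
        "null_log_likelihood": fit.null_log_likelihood,
        "pseudo_r2": fit.pseudo_r2,
        "robust_se": fit.robust_se,
    }


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        table = generate(config.synthetic)
        n_dropped = 0
        source = {"synthetic": config.synthetic.to_dict()}
    else:
        table = read_survey_csv(config.input_path, config.column_map)
        n_dropped = table.attrs.get("n_dropped", 0)
        source = {"input_path": str(config.input_path)}
    config.validate(table)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "source": source,
        "stages": list(config.stages),
        "rows_read": int(len(table) + n_dropped),
        "rows_dropped": int(n_dropped),
        "rows_analyzed": int(len(table)),
        "artifacts": {},
    }

    exposure = "kakwani"
    predictors = [exposure] + config.mediators + config.covariates

    def _run_stage(stage):
        if stage == "deprivation":
            res = group_deprivation(table, [], "kakwani", config.income_col)
            table[exposure] = res.scores.to_numpy()
            out = outdir / "deprivation.csv"
            write_table(table, out)
            sidecar = {
                str(label): {
                    "n": r.n,
                    "mean_income": r.group_mean_income,
                    "gini": r.group_gini,
                    "mean_score": float(np.mean(r.scores)),
                }
                for label, r in res.groups.items()
            }
            _write_json(sidecar, outdir / "deprivation_groups.json")
            manifest["artifacts"][stage] = ["deprivation.csv", "deprivation_groups.json"]
        elif stage == "fit":
            files = []
            for outcome in config.outcomes:
                spec = ModelSpec(outcome=outcome, predictors=predictors,
                                 fixed_effect=config.fixed_effect, robust_se=True)
                fit = fit_ordered_logit(table, spec)
                name = f"fit_{outcome}.json"
                _write_json(_fit_to_dict(fit), outdir / name)
                files.append(name)
            manifest["artifacts"][stage] = files
        elif stage == "mediation":
            results = []
            for outcome in config.outcomes:
                for mediator in config.mediators:
                    res = khb_decompose(
                        table, outcome=outcome, exposure=exposure,
                        mediator=mediator, covariates=config.covariates,
                        fixed_effect=config.fixed_effect)
                    if config.se_method == "bootstrap":
                        res = khb_se(res, "bootstrap", n_boot=config.n_boot,
                                     seed=config.seed + 1)
                    results.append(res)
            report = mediation_table(results)
            write_table(report, outdir / "mediation.tsv", sep="\t")
            manifest["artifacts"][stage] = ["mediation.tsv"]
        elif stage == "robustness":
            files = []
            for outcome in config.outcomes:
                plan = RobustnessPlan(
                    variants=list(config.robustness_variants),
                    base_spec=ModelSpec(outcome=outcome, predictors=predictors,
                                        fixed_effect=config.fixed_effect),
                    exposure=exposure, income_col=config.income_col)
                rows = []
                for variant, vr in run_robustness(table, plan).items():
                    for term, (est, se) in vr.coefficients.items():
                        rows.append({"variant": variant, "outcome": vr.outcome,
                                     "estimator": vr.estimator, "n": vr.n_obs,
                                     "term": term, "coef": est, "std_err": se,
                                     "fit_stat": vr.fit_stat})
                name = f"robustness_{outcome}.tsv"
                write_table(pd.DataFrame(rows), outdir / name, sep="\t")
                files.append(name)
            manifest["artifacts"][stage] = files
        elif stage == "subgroups":
            files = []
            for outcome in config.outcomes:
                rows = []
                for dim in config.subgroup_dimensions:
                    # the split dimension is constant within a stratum
                    spec = ModelSpec(outcome=outcome,
                                     predictors=[p for p in predictors if p != dim],
                                     fixed_effect=None, robust_se=True)
                    res = run_subgroups(table, SubgroupPlan(dimension=dim), spec,
                                        exposure=exposure,
                                        income_col=config.income_col)
                    for level, fit in res.fits.items():
                        for term in [exposure] + config.mediators:
                            rows.append({
                                "dimension": dim, "level": level,
                                "outcome": outcome, "n": fit.n_obs,
                                "term": term,
                                "coef": fit.coefficients[term],
                                "std_err": float(fit.se[term]),
                            })
                name = f"subgroups_{outcome}.tsv"
                write_table(pd.DataFrame(rows), outdir / name, sep="\t")
                files.append(name)
            manifest["artifacts"][stage] = files

    for stage in config.stages:
        logger.info("running stage '%s'", stage)
        try:
            _run_stage(stage)
        except ConfigError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            _write_json(manifest, outdir / "manifest.json")
            raise PipelineError(stage, str(exc)) from exc

    _write_json(manifest, outdir / "manifest.json")
    return manifest
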