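"""End-to-end objective runs and report assembly.

`run_objective` ties the stages together for one objective: read (or
simulate) a study table, build effect sizes, pool with subgroup analysis,
then either publication-bias diagnostics (two-arm objectives) or the
multilevel taxonomic fit (temperature).  `write_results` serialises the
bundle to stable file names: a machine-readable ``results.json`` carrying
the package version and the fully resolved configuration, plus plot-ready
delimited tables (effects, forest, funnel points/contours, variance
components).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd

from . import __version__
from .bias import egger_test, funnel_data, trim_and_fill
from .data import StudyRecord, Taxonomy, read_study_table, read_taxonomy
from .effects import effects_from_records, effects_to_frame, percent_to_q10
from .meta import RandomEffectsMeta
from .multilevel import MultilevelMeta
from .simulate import default_config, simulate_temperature_series, simulate_two_arm_studies

__all__ = ["RunConfig", "run_objective", "write_results"]


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one objective run."""

    objective: str
    seed: int
    input_path: str | None = None        # None -> simulate the default table
    taxonomy_path: str | None = None
    tau2_method: Literal["DL", "REML"] = "REML"
    outlier_rule: bool = True
    outlier_threshold: float = 1.96
    direction: str | None = None         # None -> frozen per-objective convention
    backend: Literal["mcmc", "reml"] = "mcmc"
    iterations: int = 13_000
    burnin: int = 3_000
    thin: int = 10
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(f"input path does not exist: {self.input_path}")
        if self.taxonomy_path is not None and not Path(self.taxonomy_path).exists():
            raise FileNotFoundError(f"taxonomy path does not exist: {self.taxonomy_path}")


def _load_records(config: RunConfig) -> list[StudyRecord]:
    if config.input_path is not None:
        return read_study_table(config.input_path, config.objective)
    sim = default_config(config.objective, config.seed)
    if config.objective == "temperature":
        return simulate_temperature_series(sim)
    return simulate_two_arm_studies(sim)


def run_objective(config: RunConfig) -> dict:
    """Execute one objective end to end; returns the report bundle."""
    records = _load_records(config)
    taxonomy = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
    if taxonomy is not None:
        for rec in records:
            taxonomy.resolve(rec.taxonomy_path)

    effects = effects_from_records(records, direction=config.direction)
    model = RandomEffectsMeta(effects)
    sub = model.fit_subgroups(method=config.tau2_method)
    pooled = sub.overall

    bundle: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "k": model.k,
        "pooled": pooled.to_dict(),
        "subgroups": {label: r.to_dict() for label, r in sub.per_subgroup.items()},
        "tables": {
            "effects": effects_to_frame(effects),
            "forest": model.forest_frame(config.tau2_method),
        },
    }

    if config.outlier_rule and model.k >= 3:
        out = model.detect_outliers(config.outlier_threshold, config.tau2_method)
        bundle["outliers"] = {
            "removed_ids": list(out.removed_ids),
            "threshold": out.threshold,
            "refit": out.refit.to_dict(),
        }

    if config.objective == "temperature":
        ml = MultilevelMeta(effects, taxonomy)
        res = ml.fit(config.backend, iterations=config.iterations,
                     burnin=config.burnin, thin=config.thin,
                     seed=config.seed if config.backend == "mcmc" else None)
        bundle["multilevel"] = res.to_dict()
        bundle["multilevel"]["q10"] = percent_to_q10(res.mean)
        bundle["tables"]["variance_components"] = ml.variance_components_frame(res)
        bundle["tables"]["per_order_means"] = pd.DataFrame(
            [dict(order=o, mean=m, ci_low=l, ci_high=h)
             for o, (m, l, h) in res.per_order_means.items()])
    else:
        egger = egger_test(effects)
        tf = trim_and_fill(effects, method=config.tau2_method)
        funnel = funnel_data(effects, pooled)
        bundle["bias"] = {
            "egger": dict(intercept=egger.intercept, se=egger.se_intercept,
                          t=egger.t, df=egger.df, p=egger.p,
                          ci_low=egger.ci[0], ci_high=egger.ci[1]),
            "trim_and_fill": dict(k0=tf.k0, side=tf.side,
                                  estimator=tf.estimator_tag,
                                  adjusted=tf.adjusted.to_dict()),
        }
        bundle["tables"]["funnel_points"] = funnel.points
        bundle["tables"]["funnel_contours"] = funnel.contours
    return bundle


def write_results(bundle: dict, out_dir: str | Path) -> Path:
    """Write the report bundle under ``out_dir`` with stable file names."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = bundle.get("tables", {})
    for name, frame in tables.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    payload = {k: v for k, v in bundle.items() if k != "tables"}
    payload["table_files"] = sorted(f"{name}.csv" for name in tables)
    results_path = out / "results.json"
    results_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return results_path
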