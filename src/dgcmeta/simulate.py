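"""Synthetic study-table generators.

The extracted literature dataset behind the analyses lives in an external
archive, so every pipeline stage is exercised on synthetic tables generated
here.  Each generator is a pure function of its configuration and seed and
emits the same structures the readers in :mod:`dgcmeta.data` produce, so the
full pipeline runs closed-loop against known truths.

Default configurations mirror the conditions of the three study objectives:

* hygric — 42 two-arm water-loss comparisons across 3 orders, true effect
  -3.27 on the Hedges-g scale with large between-study variance (high I²);
* chthonic (hyperoxia / hypoxia) — 29 two-arm metabolic-rate comparisons
  across 4 orders, true effects 0.21 and 0.27 with zero and small
  between-study variance respectively;
* temperature — 30 multi-temperature series across a 9-order taxonomy with a
  true log-linear slope of ln(1.0813) per °C (8.13 percent per °C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ArmSummary, StudyRecord, Taxonomy, TemperatureSeries
from .effects import EffectSize, effects_from_records

__all__ = [
    "SimulationConfig",
    "default_config",
    "simulate_two_arm_studies",
    "simulate_temperature_series",
    "simulate_taxonomic_effects",
    "apply_publication_censoring",
]

_ORDER_POOL = ("Blattodea", "Coleoptera", "Orthoptera", "Diptera",
               "Lepidoptera", "Hymenoptera", "Hemiptera", "Phasmatodea",
               "Grylloblattodea")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study set.  ``seed`` is mandatory."""

    seed: int
    objective: str = "hygric"
    k_studies: int = 42
    true_effect: float = -3.27          # Hedges-g scale, or beta1 for temperature
    tau2: float = 4.0                   # between-study variance of the true effect
    arm_n_range: tuple[int, int] = (5, 15)
    arm_sd_range: tuple[float, float] = (0.3, 1.0)
    baseline_mean: float = 5.0          # reference-arm population mean
    temperature_grid: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0)
    baseline_rate: float = 0.5          # ml/g/h at the reference temperature
    reference_temperature: float = 25.0
    noise_sd_log: float = 0.15          # log-scale SD of individual rates
    noise_model: Literal["lognormal", "additive"] = "lognormal"
    taxonomy_shape: tuple[int, int, int] = (3, 2, 2)  # orders, families/order, species/family
    var_order: float = 0.0
    var_family: float = 0.0
    var_species: float = 0.0
    sampling_variance: float = 2.0      # v_i for directly simulated effects
    censoring: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau2", "var_order", "var_family", "var_species"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.censoring <= 1.0):
            raise ValueError("censoring severity must lie in [0, 1]")
        if self.arm_n_range[0] < 2:
            raise ValueError("arm n must be at least 2")
        if self.objective == "temperature" and self.baseline_rate <= 0:
            raise ValueError("baseline rate must be positive")
        if self.taxonomy_shape[0] == 1 and self.var_order > 0:
            raise ValueError("order variance is unidentifiable with a single order")


def default_config(objective: str, seed: int) -> SimulationConfig:
    """The study conditions each objective's synthetic dataset emulates."""
    if objective == "hygric":
        return SimulationConfig(seed=seed, objective=objective, k_studies=42,
                                true_effect=-3.27, tau2=4.0,
                                taxonomy_shape=(3, 2, 3))
    if objective == "chthonic_hyperoxia":
        return SimulationConfig(seed=seed, objective=objective, k_studies=29,
                                true_effect=0.21, tau2=0.0,
                                taxonomy_shape=(4, 2, 1))
    if objective == "chthonic_hypoxia":
        return SimulationConfig(seed=seed, objective=objective, k_studies=29,
                                true_effect=0.27, tau2=0.045,
                                taxonomy_shape=(4, 2, 1))
    if objective == "temperature":
        return SimulationConfig(seed=seed, objective=objective, k_studies=30,
                                true_effect=math.log(1.0813), tau2=2.5e-4,
                                taxonomy_shape=(9, 2, 2),
                                var_order=4.0, var_family=1.0, var_species=1.0)
    raise ValueError(f"unknown objective {objective!r}")


def _taxon_assignments(shape: tuple[int, int, int], k: int,
                       rng: np.random.Generator) -> list[tuple[str, str, str]]:
    n_ord, n_fam, n_sp = shape
    orders = _ORDER_POOL[:n_ord] if n_ord <= len(_ORDER_POOL) else tuple(
        f"Order{i+1:02d}" for i in range(n_ord))
    paths = []
    for oi, o in enumerate(orders):
        for fi in range(n_fam):
            fam = f"{o[:4]}idae{fi+1:02d}"
            for si in range(n_sp):
                paths.append((o, fam, f"{o[:4].lower()}_sp{fi+1}{si+1}"))
    # cycle through species so every order is represented
    return [paths[i % len(paths)] for i in range(k)]


def simulate_two_arm_studies(config: SimulationConfig) -> list[StudyRecord]:
    """Two-arm studies whose Hedges' g has expectation theta_i ~ N(mu, tau²).

    Both arms share a population SD sigma; the comparison-arm mean is offset
    by theta_i*sigma, arm means are drawn from their sampling distributions
    N(mu, sigma²/n) and arm SDs from sigma²·chi²(n-1)/(n-1), so the computed
    g is an (approximately) unbiased estimate of theta_i.
    """
    rng = np.random.default_rng(config.seed)
    units = "mg/h" if config.objective == "hygric" else "ml/g/h"
    paths = _taxon_assignments(config.taxonomy_shape, config.k_studies, rng)
    records = []
    for i in range(config.k_studies):
        theta = rng.normal(config.true_effect, math.sqrt(config.tau2))
        n1 = int(rng.integers(config.arm_n_range[0], config.arm_n_range[1] + 1))
        n2 = int(rng.integers(config.arm_n_range[0], config.arm_n_range[1] + 1))
        sigma = rng.uniform(*config.arm_sd_range)
        mu_ref = config.baseline_mean
        mu_cmp = mu_ref + theta * sigma
        m1 = rng.normal(mu_ref, sigma / math.sqrt(n1))
        m2 = rng.normal(mu_cmp, sigma / math.sqrt(n2))
        s1 = sigma * math.sqrt(rng.chisquare(n1 - 1) / (n1 - 1))
        s2 = sigma * math.sqrt(rng.chisquare(n2 - 1) / (n2 - 1))
        order, fam, sp = paths[i]
        records.append(StudyRecord(
            study_id=f"{config.objective}_{i+1:03d}", order=order, family=fam,
            species=sp, objective=config.objective,
            arms=(ArmSummary(m1, s1, n1, units),
                  ArmSummary(m2, s2, n2, units)),
        ))
    return records


def simulate_temperature_series(config: SimulationConfig) -> list[StudyRecord]:
    """Multi-temperature metabolic-rate series with per-study slopes.

    Each study's slope is beta1_i ~ N(true beta1 + taxonomic deviations,
    tau2); individual rates at temperature T are lognormal around
    exp(beta0 + beta1_i*T) (or additive Gaussian under the misspecification
    toggle), and the emitted per-temperature mean, SD and n are the summary
    statistics of those individuals.  The configured taxonomic variance
    components are on the percent-per-°C scale and enter the slope as
    deviations divided by 100 (exact for small slopes).
    """
    if len(config.temperature_grid) < 2:
        raise ValueError("need at least two temperatures in the grid")
    rng = np.random.default_rng(config.seed)
    paths = _taxon_assignments(config.taxonomy_shape, config.k_studies, rng)
    u_o: dict[str, float] = {}
    u_f: dict[tuple[str, str], float] = {}
    u_s: dict[tuple[str, str, str], float] = {}
    for p in paths:
        u_o.setdefault(p[0], rng.normal(0.0, math.sqrt(config.var_order)))
        u_f.setdefault((p[0], p[1]), rng.normal(0.0, math.sqrt(config.var_family)))
        u_s.setdefault(p, rng.normal(0.0, math.sqrt(config.var_species)))
    records = []
    for i in range(config.k_studies):
        p = paths[i]
        taxon_shift = (u_o[p[0]] + u_f[(p[0], p[1])] + u_s[p]) / 100.0
        beta1 = rng.normal(config.true_effect + taxon_shift, math.sqrt(config.tau2))
        beta0 = math.log(config.baseline_rate) - beta1 * config.reference_temperature
        temps, means, sds, ns = [], [], [], []
        for t in config.temperature_grid:
            n = int(rng.integers(config.arm_n_range[0], config.arm_n_range[1] + 1))
            loc = beta0 + beta1 * t
            if config.noise_model == "lognormal":
                individuals = np.exp(rng.normal(loc, config.noise_sd_log, size=n))
            else:
                mu_t = math.exp(loc)
                individuals = rng.normal(mu_t, config.noise_sd_log * mu_t, size=n)
                individuals = np.clip(individuals, 1e-9, None)
            temps.append(float(t))
            means.append(float(individuals.mean()))
            sds.append(float(individuals.std(ddof=1)))
            ns.append(n)
        order, fam, sp = paths[i]
        records.append(StudyRecord(
            study_id=f"temp_{i+1:03d}", order=order, family=fam, species=sp,
            objective="temperature",
            series=TemperatureSeries(tuple(temps), tuple(means), tuple(sds),
                                     tuple(ns)),
        ))
    return records


def simulate_taxonomic_effects(
    config: SimulationConfig,
) -> tuple[list[EffectSize], Taxonomy]:
    """Effect sizes with taxonomic structure and known sampling variances.

    y_i = true_effect + u_order + u_family + u_species + e_i with
    e_i ~ N(0, sampling_variance); taxonomic deviations are drawn from their
    configured variances over the configured (orders × families × species)
    shape.  Effects are reported on the percent-per-°C scale.
    """
    rng = np.random.default_rng(config.seed)
    n_ord, n_fam, n_sp = config.taxonomy_shape
    paths = _taxon_assignments(config.taxonomy_shape, config.k_studies, rng)
    all_paths = list(dict.fromkeys(
        _taxon_assignments(config.taxonomy_shape, n_ord * n_fam * n_sp, rng)))
    orders = list(dict.fromkeys(p[0] for p in all_paths))
    families = list(dict.fromkeys((p[0], p[1]) for p in all_paths))
    species = all_paths
    u_o = {o: rng.normal(0.0, math.sqrt(config.var_order)) for o in orders}
    u_f = {f: rng.normal(0.0, math.sqrt(config.var_family)) for f in families}
    u_s = {s: rng.normal(0.0, math.sqrt(config.var_species)) for s in species}
    effects = []
    for i, p in enumerate(paths):
        v_i = config.sampling_variance
        y = (config.true_effect + u_o[p[0]] + u_f[(p[0], p[1])] + u_s[p]
             + rng.normal(0.0, math.sqrt(v_i)))
        effects.append(EffectSize(value=float(y), variance=float(v_i),
                                  study_id=f"tax_{i+1:03d}",
                                  family_tag="percent_per_degC",
                                  subgroup=p[0], taxonomy_path=p))
    taxonomy = Taxonomy(all_paths)
    return effects, taxonomy


def apply_publication_censoring(
    items: Sequence[EffectSize] | Sequence[StudyRecord],
    severity: float,
    seed: int,
    favored: Literal["negative", "positive"] = "negative",
    p_threshold: float = 0.05,
) -> list:
    """Remove studies whose result fails to support the favored direction.

    Each item whose one-sided p-value against the favored direction exceeds
    ``p_threshold`` is dropped with probability ``severity``.  Works on
    effect-size lists directly; study records are converted to effects for
    the decision but returned unchanged when kept.
    """
    if not (0.0 <= severity <= 1.0):
        raise ValueError("severity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if len(items) == 0:
        return []
    if isinstance(items[0], StudyRecord):
        effects = effects_from_records(items)
    else:
        effects = list(items)
    kept = []
    for item, e in zip(items, effects):
        z = e.value / e.se
        p_one = stats.norm.cdf(z) if favored == "negative" else stats.norm.sf(z)
        if p_one > p_threshold and rng.random() < severity:
            continue
        kept.append(item)
    return kept
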