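"""Effect-size construction.

Two effect-size families are used:

* **Hedges' g** — small-sample-corrected standardized mean difference for
  two-arm comparisons (respiratory vs cuticular water loss; normoxia vs
  altered-oxygen metabolic rate).

* **Percent change per °C** — from a per-study log-linear regression of
  ln(metabolic rate) on temperature, the slope ``b1`` is transformed to
  ``ES = (exp(b1) - 1) * 100`` with delta-method sampling variance
  ``V = 100**2 * exp(2*b1) * SE**2``, where ``SE**2`` is the slope sampling
  variance assembled from the per-temperature dispersions via the delta
  method ``sigma_LM = sigma_M / mean`` (SD of the log of a rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data import ArmSummary, StudyRecord, TemperatureSeries

__all__ = [
    "EffectSize",
    "SlopeFit",
    "hedges_g",
    "log_linear_slope",
    "slope_to_percent_es",
    "percent_to_q10",
    "effects_from_records",
    "effects_to_frame",
    "effects_from_frame",
    "DIRECTION_CONVENTIONS",
]

#: Frozen per-objective arm-subtraction conventions.  For the hygric objective
#: the comparison arm is respiratory water loss and the reference is cuticular,
#: so a negative g means the open-spiracle phase loses less water; for the
#: chthonic objectives the comparison arm is the altered-oxygen condition, so a
#: positive g favors normoxia.
DIRECTION_CONVENTIONS = {
    "hygric": "comparison_minus_reference",
    "chthonic_hyperoxia": "comparison_minus_reference",
    "chthonic_hypoxia": "comparison_minus_reference",
}


@dataclass(frozen=True)
class EffectSize:
    """A standardized effect with its sampling variance and study identity."""

    value: float
    variance: float
    study_id: str
    family_tag: Literal["hedges_g", "percent_per_degC"]
    subgroup: str = ""
    taxonomy_path: tuple[str, str, str] | None = None

    def __post_init__(self) -> None:
        if not (self.variance > 0) or not math.isfinite(self.variance):
            raise ValueError(f"effect-size variance must be > 0, got {self.variance}")
        if self.family_tag not in ("hedges_g", "percent_per_degC"):
            raise ValueError(f"unknown family_tag {self.family_tag!r}")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class SlopeFit:
    """Log-linear fit of ln(rate) on temperature with its variance bookkeeping.

    ``sigma1_sq`` pools the within-temperature log-scale variation,
    sum((n-1) * sigma_LM**2); ``sigma2_sq`` is the n-weighted lack-of-fit sum
    of squares, sum(n * (lnR - lnf)**2); the slope sampling variance is
    ``SE**2 = ((sigma1_sq + sigma2_sq) / (sum(n) - 2)) / sum(n*(x - xbar)**2)``
    with the n-weighted temperature mean ``xbar``.
    """

    beta0: float
    beta1: float
    se_slope: float
    sigma1_sq: float
    sigma2_sq: float
    n_total: int
    fitted: tuple[float, ...]

    @property
    def var_slope(self) -> float:
        return self.se_slope**2


def hedges_g(
    reference: ArmSummary,
    comparison: ArmSummary,
    direction: str = "comparison_minus_reference",
    *,
    study_id: str = "",
    subgroup: str = "",
    taxonomy_path: tuple[str, str, str] | None = None,
    small_sample_variance: bool = False,
) -> EffectSize:
    """Hedges' g standardized mean difference between two arms.

    g = J * (mean_num - mean_den) / S_pooled, with the pooled SD across arms
    and the small-sample correction J = 1 - 3/(4*(n1+n2-2) - 1).  The
    ``direction`` flag fixes which arm is subtracted.  The default sampling
    variance is the large-sample form (n1+n2)/(n1*n2) + g**2/(2*(n1+n2));
    ``small_sample_variance=True`` uses J**2 times the same form evaluated at
    Cohen's d instead.
    """
    ref = reference.as_sd()
    cmp_ = comparison.as_sd()
    n1, n2 = ref.n, cmp_.n
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both arms need n >= 2, got {n1} and {n2}")
    if ref.sd == 0 and cmp_.sd == 0:
        raise ValueError("both arm SDs are zero: standardized difference is degenerate")
    if direction == "comparison_minus_reference":
        diff = cmp_.mean - ref.mean
    elif direction == "reference_minus_comparison":
        diff = ref.mean - cmp_.mean
    else:
        raise ValueError(f"unknown direction {direction!r}")
    df = n1 + n2 - 2
    s_pooled = math.sqrt(((n1 - 1) * ref.sd**2 + (n2 - 1) * cmp_.sd**2) / df)
    d = diff / s_pooled
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    n_tot = n1 + n2
    if small_sample_variance:
        var = j**2 * (n_tot / (n1 * n2) + d**2 / (2.0 * n_tot))
    else:
        var = n_tot / (n1 * n2) + g**2 / (2.0 * n_tot)
    return EffectSize(value=g, variance=var, study_id=study_id,
                      family_tag="hedges_g", subgroup=subgroup,
                      taxonomy_path=taxonomy_path)


def log_linear_slope(series: TemperatureSeries, *, weighted: bool = True) -> SlopeFit:
    """Fit ln(mean rate) on temperature and assemble the slope sampling variance.

    The regression is n-weighted least squares on the per-temperature log
    means (``weighted=False`` gives the unweighted fit for sensitivity runs);
    the sampling variance of the slope combines the within-temperature
    log-scale variance (via sigma_LM = sigma_M / mean) and the lack-of-fit
    residual sum, on sum(n) - 2 degrees of freedom.
    """
    x = np.asarray(series.temperatures, dtype=float)
    ln_r = np.log(np.asarray(series.means, dtype=float))
    n = np.asarray(series.ns, dtype=float)
    sd = series.sds()
    n_total = float(n.sum())
    if n_total <= 2:
        raise ValueError("slope variance needs sum(n) > 2 degrees of freedom")

    w = n if weighted else np.ones_like(n)
    xbar_fit = np.sum(w * x) / np.sum(w)
    ybar_fit = np.sum(w * ln_r) / np.sum(w)
    sxx_fit = np.sum(w * (x - xbar_fit) ** 2)
    if sxx_fit <= 0:
        raise ValueError("need at least two distinct temperatures")
    beta1 = float(np.sum(w * (x - xbar_fit) * (ln_r - ybar_fit)) / sxx_fit)
    beta0 = float(ybar_fit - beta1 * xbar_fit)
    fitted = beta0 + beta1 * x

    # variance bookkeeping is always n-weighted, exactly as defined
    sigma_lm = sd / np.asarray(series.means, dtype=float)
    sigma1_sq = float(np.sum((n - 1.0) * sigma_lm**2))
    sigma2_sq = float(np.sum(n * (ln_r - fitted) ** 2))
    xbar = np.sum(n * x) / n_total
    sxx = float(np.sum(n * (x - xbar) ** 2))
    se2 = ((sigma1_sq + sigma2_sq) / (n_total - 2.0)) / sxx
    if se2 <= 0:
        raise ValueError("slope sampling variance is zero: series has no dispersion")
    return SlopeFit(beta0=beta0, beta1=beta1, se_slope=math.sqrt(se2),
                    sigma1_sq=sigma1_sq, sigma2_sq=sigma2_sq,
                    n_total=int(n_total), fitted=tuple(float(f) for f in fitted))


def slope_to_percent_es(
    fit: SlopeFit,
    *,
    study_id: str = "",
    subgroup: str = "",
    taxonomy_path: tuple[str, str, str] | None = None,
) -> EffectSize:
    """Transform a log-linear slope to percent change in rate per °C.

    ES = (exp(b1) - 1) * 100; V = 100**2 * exp(2*b1) * SE**2 (delta method).
    """
    if not (math.isfinite(fit.beta1) and math.isfinite(fit.se_slope)):
        raise ValueError("slope fit has non-finite beta1 or SE")
    value = (math.exp(fit.beta1) - 1.0) * 100.0
    variance = 100.0**2 * math.exp(2.0 * fit.beta1) * fit.var_slope
    return EffectSize(value=value, variance=variance, study_id=study_id,
                      family_tag="percent_per_degC", subgroup=subgroup,
                      taxonomy_path=taxonomy_path)


def percent_to_q10(percent: float) -> float:
    """Q10 implied by a percent change per °C: Q10 = (1 + pct/100)**10."""
    if percent <= -100:
        raise ValueError("percent change per °C must exceed -100")
    return (1.0 + percent / 100.0) ** 10


def effects_from_records(
    records: Sequence[StudyRecord],
    *,
    direction: str | None = None,
    weighted: bool = True,
) -> list[EffectSize]:
    """Compute the appropriate effect size for each study record.

    Two-arm records yield Hedges' g under the objective's frozen direction
    convention (overridable via ``direction``); temperature records yield the
    percent-change-per-°C effect from the log-linear slope.
    """
    out: list[EffectSize] = []
    for rec in records:
        if rec.objective == "temperature":
            fit = log_linear_slope(rec.series, weighted=weighted)
            out.append(slope_to_percent_es(
                fit, study_id=rec.study_id, subgroup=rec.order,
                taxonomy_path=rec.taxonomy_path))
        else:
            conv = direction or DIRECTION_CONVENTIONS[rec.objective]
            ref, cmp_ = rec.arms
            out.append(hedges_g(
                ref, cmp_, conv, study_id=rec.study_id, subgroup=rec.order,
                taxonomy_path=rec.taxonomy_path))
    return out


def effects_to_frame(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Export effects as a flat table (study_id, taxonomy, value, variance, se)."""
    rows = []
    for e in effects:
        order, fam, sp = e.taxonomy_path if e.taxonomy_path else (e.subgroup, "", "")
        rows.append(dict(study_id=e.study_id, order=order, family=fam, species=sp,
                         family_tag=e.family_tag, value=e.value,
                         variance=e.variance, se=e.se))
    return pd.DataFrame(rows)


def effects_from_frame(df: pd.DataFrame) -> list[EffectSize]:
    """Rebuild effect sizes from an exported effects table."""
    out = []
    for r in df.itertuples(index=False):
        path = (str(r.order), str(getattr(r, "family", "")), str(getattr(r, "species", "")))
        out.append(EffectSize(value=float(r.value), variance=float(r.variance),
                              study_id=str(r.study_id), family_tag=str(r.family_tag),
                              subgroup=str(r.order), taxonomy_path=path))
    return out
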