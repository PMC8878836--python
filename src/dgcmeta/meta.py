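"""Inverse-variance random-effects meta-analysis.

`RandomEffectsMeta` is a model object built from a list of
:class:`~dgcmeta.effects.EffectSize` (or an exported effects table); its
:meth:`~RandomEffectsMeta.fit` estimates the between-study variance tau² (by
DerSimonian–Laird or REML), pools the effects with weights 1/(v_i + tau²),
and returns a :class:`MetaResults` carrying the estimate, its 95% CI, Wald
z/p, Cochran's Q and I².  Subgroup analysis refits each subgroup with its own
tau²; outlier detection uses leave-one-out externally standardized residuals.

Confidence intervals use the normal quantile (±1.96·se) throughout, matching
the Wald z statistics reported alongside them; no Knapp–Hartung adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectSize, effects_from_frame

__all__ = [
    "RandomEffectsMeta",
    "MetaResults",
    "SubgroupResults",
    "OutlierResults",
    "estimate_tau2",
    "pool_random_effects",
    "subgroup_analysis",
    "detect_outliers",
    "sensitivity_filter",
]

Z95 = stats.norm.ppf(0.975)


def _check_effects(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) == 0:
        raise ValueError("no effect sizes supplied")
    tags = {e.family_tag for e in effects}
    if len(tags) > 1:
        raise ValueError(f"mixed effect-size families cannot be pooled: {sorted(tags)}")
    y = np.array([e.value for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    return y, v


def estimate_tau2(
    effects: Sequence[EffectSize] | None = None,
    method: Literal["DL", "REML"] = "REML",
    *,
    y: np.ndarray | None = None,
    v: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> float:
    """Between-study variance tau² by DerSimonian–Laird or iterative REML.

    DL: tau² = max(0, (Q - df)/C) with C = sum(w) - sum(w²)/sum(w), w = 1/v.
    REML: fixed-point iteration of the restricted-likelihood estimating
    equation to ``tol``; non-convergence falls back to DL with a warning.
    """
    if y is None or v is None:
        y, v = _check_effects(effects)
    k = len(y)
    if k < 2:
        raise ValueError("tau² estimation needs at least two effects")
    if method == "DL":
        return _tau2_dl(y, v)
    if method != "REML":
        raise ValueError(f"unknown tau² method {method!r}")
    tau2 = _tau2_dl(y, v)
    for _ in range(maxiter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        new = np.sum(w**2 * ((y - mu) ** 2 - v)) / np.sum(w**2) + 1.0 / np.sum(w)
        new = max(0.0, float(new))
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    warnings.warn("REML tau² did not converge; falling back to DerSimonian-Laird",
                  stacklevel=2)
    return _tau2_dl(y, v)


def _tau2_dl(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    sw = np.sum(w)
    mu_fe = np.sum(w * y) / sw
    q = float(np.sum(w * (y - mu_fe) ** 2))
    df = len(y) - 1
    c = sw - np.sum(w**2) / sw
    return max(0.0, (q - df) / c)


@dataclass(frozen=True)
class MetaResults:
    """Pooled random-effects estimate with heterogeneity statistics."""

    estimate: float
    se: float
    tau2: float
    Q: float
    df: int
    I2: float
    k: int
    method_tag: str
    family_tag: str

    @property
    def ci_half_width(self) -> float:
        return Z95 * self.se

    @property
    def ci(self) -> tuple[float, float]:
        return (self.estimate - self.ci_half_width, self.estimate + self.ci_half_width)

    @property
    def z(self) -> float:
        return self.estimate / self.se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))

    def summary(self) -> str:
        lo, hi = self.ci
        lines = [
            "Random-effects meta-analysis",
            "=" * 44,
            f"k (effects)        {self.k:>12d}",
            f"family             {self.family_tag:>12s}",
            f"tau^2 ({self.method_tag})       {self.tau2:>12.4f}",
            f"estimate           {self.estimate:>12.4f}",
            f"95% CI             [{lo:.4f}, {hi:.4f}]",
            f"z                  {self.z:>12.3f}",
            f"p (two-sided)      {self.p:>12.4g}",
            f"Q (df={self.df:d})          {self.Q:>12.3f}",
            f"I^2                {self.I2:>11.1f}%",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return dict(estimate=self.estimate, se=self.se,
                    ci_half_width=self.ci_half_width, ci_low=self.ci[0],
                    ci_high=self.ci[1], z=self.z, p=self.p, tau2=self.tau2,
                    Q=self.Q, df=self.df, I2=self.I2, k=self.k,
                    method_tag=self.method_tag, family_tag=self.family_tag)


@dataclass(frozen=True)
class SubgroupResults:
    """Independent pooled results per subgroup, plus the overall pooling."""

    per_subgroup: dict[str, MetaResults]
    overall: MetaResults

    def summary(self) -> str:
        lines = [self.overall.summary(), "", "Subgroups (separate tau^2 each)",
                 "-" * 44]
        for label, res in self.per_subgroup.items():
            lo, hi = res.ci
            lines.append(
                f"{label:<16s} k={res.k:<3d} est={res.estimate:8.3f} "
                f"[{lo:.3f}, {hi:.3f}]  I^2={res.I2:5.1f}%  p={res.p:.3g}")
        return "\n".join(lines)


@dataclass(frozen=True)
class OutlierResults:
    """Leave-one-out standardized residuals, flags, and the re-pooled fit."""

    residuals: np.ndarray
    flags: np.ndarray
    threshold: float
    refit: MetaResults
    removed_ids: tuple[str, ...]


class RandomEffectsMeta:
    """Random-effects meta-analysis model over a homogeneous set of effects.

    Parameters
    ----------
    effects
        Effect sizes sharing one ``family_tag``.  All carry known sampling
        variances; heterogeneity beyond those variances is absorbed by tau².
    """

    def __init__(self, effects: Sequence[EffectSize]):
        self.effects = list(effects)
        self.y, self.v = _check_effects(self.effects)
        self.family_tag = self.effects[0].family_tag

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RandomEffectsMeta":
        """Build from an exported effects table (see ``effects_to_frame``)."""
        return cls(effects_from_frame(df))

    @property
    def k(self) -> int:
        return len(self.y)

    def fit(self, method: Literal["DL", "REML"] = "REML") -> MetaResults:
        """Estimate tau² and pool with inverse-variance random-effects weights."""
        y, v = self.y, self.v
        k = self.k
        if k == 1:
            warnings.warn("single effect: returning the study's own estimate; "
                          "heterogeneity undefined (reported as 0)", stacklevel=2)
            return MetaResults(estimate=float(y[0]), se=float(np.sqrt(v[0])),
                               tau2=0.0, Q=0.0, df=0, I2=0.0, k=1,
                               method_tag=method, family_tag=self.family_tag)
        tau2 = estimate_tau2(self.effects, method)
        w_star = 1.0 / (v + tau2)
        est = float(np.sum(w_star * y) / np.sum(w_star))
        se = float(1.0 / math.sqrt(np.sum(w_star)))
        w_fe = 1.0 / v
        mu_fe = np.sum(w_fe * y) / np.sum(w_fe)
        q = float(np.sum(w_fe * (y - mu_fe) ** 2))
        df = k - 1
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
        return MetaResults(estimate=est, se=se, tau2=tau2, Q=q, df=df, I2=i2,
                           k=k, method_tag=method, family_tag=self.family_tag)

    def fit_subgroups(
        self,
        labels: Sequence[str] | None = None,
        method: Literal["DL", "REML"] = "REML",
    ) -> SubgroupResults:
        """Pool each subgroup independently (own tau² each) plus overall.

        ``labels`` defaults to each effect's ``subgroup`` (insect order).
        """
        if labels is None:
            labels = [e.subgroup for e in self.effects]
        labels = [str(l) for l in labels]
        if len(labels) != self.k:
            raise ValueError("one label per effect required")
        if any(not l for l in labels):
            raise ValueError("unlabeled effect in subgroup analysis")
        per: dict[str, MetaResults] = {}
        for label in dict.fromkeys(labels):  # preserve first-seen order
            sub = [e for e, l in zip(self.effects, labels) if l == label]
            per[label] = RandomEffectsMeta(sub).fit(method)
        return SubgroupResults(per_subgroup=per, overall=self.fit(method))

    def detect_outliers(
        self,
        threshold: float = 1.96,
        method: Literal["DL", "REML"] = "REML",
    ) -> OutlierResults:
        """Flag effects by leave-one-out externally standardized residuals.

        For each effect i the model is refitted without it; the residual
        (y_i - est_{-i}) is standardized by sqrt(v_i + tau²_{-i} + se_{-i}²)
        and flagged when its magnitude exceeds ``threshold``.
        """
        if self.k < 3:
            raise ValueError("outlier detection needs at least three effects")
        resid = np.empty(self.k)
        for i in range(self.k):
            rest = [e for j, e in enumerate(self.effects) if j != i]
            r = RandomEffectsMeta(rest).fit(method)
            denom = math.sqrt(self.v[i] + r.tau2 + r.se**2)
            resid[i] = (self.y[i] - r.estimate) / denom
        flags = np.abs(resid) > threshold
        kept = [e for e, f in zip(self.effects, flags) if not f]
        if not kept:
            raise ValueError("all effects flagged as outliers; nothing to re-pool")
        refit = RandomEffectsMeta(kept).fit(method)
        removed = tuple(e.study_id for e, f in zip(self.effects, flags) if f)
        return OutlierResults(residuals=resid, flags=flags, threshold=threshold,
                              refit=refit, removed_ids=removed)

    def forest_frame(self, method: Literal["DL", "REML"] = "REML") -> pd.DataFrame:
        """Plot-ready forest table: per-effect rows plus a pooled summary row."""
        res = self.fit(method)
        w = 1.0 / (self.v + res.tau2)
        w_pct = 100.0 * w / np.sum(w)
        rows = []
        for e, wp in zip(self.effects, w_pct):
            rows.append(dict(row_type="effect", label=e.study_id,
                             subgroup=e.subgroup, value=e.value,
                             ci_low=e.value - Z95 * e.se,
                             ci_high=e.value + Z95 * e.se, weight_pct=wp))
        rows.append(dict(row_type="summary", label="pooled", subgroup="",
                         value=res.estimate, ci_low=res.ci[0],
                         ci_high=res.ci[1], weight_pct=100.0))
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Functional surface (thin wrappers over the model object)

def pool_random_effects(effects: Sequence[EffectSize],
                        method: Literal["DL", "REML"] = "REML") -> MetaResults:
    return RandomEffectsMeta(effects).fit(method)


def subgroup_analysis(effects: Sequence[EffectSize],
                      labels: Sequence[str] | None = None,
                      method: Literal["DL", "REML"] = "REML") -> SubgroupResults:
    return RandomEffectsMeta(effects).fit_subgroups(labels, method)


def detect_outliers(effects: Sequence[EffectSize], threshold: float = 1.96,
                    method: Literal["DL", "REML"] = "REML") -> OutlierResults:
    return RandomEffectsMeta(effects).detect_outliers(threshold, method)


def sensitivity_filter(effects: Sequence[EffectSize],
                       rule: str = "drop_negative_percent") -> list[EffectSize]:
    """Sensitivity subset: drop percent-per-°C effects with negative values."""
    if rule != "drop_negative_percent":
        raise ValueError(f"unknown sensitivity rule {rule!r}")
    if any(e.family_tag != "percent_per_degC" for e in effects):
        raise ValueError("drop_negative_percent applies to percent-per-°C effects only")
    kept = [e for e in effects if e.value >= 0]
    removed = [e.study_id for e in effects if e.value < 0]
    if removed:
        warnings.warn(f"sensitivity filter removed {len(removed)} effect(s): {removed}",
                      stacklevel=2)
    return kept
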