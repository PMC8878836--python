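"""Publication-bias diagnostics: Egger regression, trim-and-fill, funnel data.

Egger's test uses the classical precision parameterization: the standardized
effect y_i/se_i is regressed on precision 1/se_i by OLS, and the intercept —
zero in an unbiased funnel — is tested with a t statistic on k-2 degrees of
freedom.

Trim-and-fill is the Duval–Tweedie rank-based method: the number k0 of
suppressed studies on one side of the funnel is estimated (L0 or R0
estimator) under fixed-effect trimming, the k0 most extreme studies are
iteratively trimmed until k0 stabilizes, and mirrored counterparts are
imputed about the trimmed centre before a final random-effects pooling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .effects import EffectSize
from .meta import MetaResults, RandomEffectsMeta, pool_random_effects

__all__ = ["EggerResult", "TrimFillResult", "FunnelData",
           "egger_test", "trim_and_fill", "funnel_data"]

#: pseudo-confidence contour levels drawn on funnel plots
FUNNEL_LEVELS = (0.95, 0.99, 0.9975)


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se_intercept: float
    df: int

    @property
    def t(self) -> float:
        return self.intercept / self.se_intercept

    @property
    def p(self) -> float:
        return float(2.0 * stats.t.sf(abs(self.t), self.df))

    @property
    def ci(self) -> tuple[float, float]:
        half = stats.t.ppf(0.975, self.df) * self.se_intercept
        return (self.intercept - half, self.intercept + half)

    def summary(self) -> str:
        lo, hi = self.ci
        return (f"Egger regression test: intercept={self.intercept:.3f} "
                f"(95% CI {lo:.3f} to {hi:.3f}), t={self.t:.3f}, "
                f"df={self.df}, p={self.p:.4g}")


@dataclass(frozen=True)
class TrimFillResult:
    k0: int
    side: Literal["left", "right"]
    adjusted: MetaResults
    estimator_tag: Literal["L0", "R0"]
    imputed: tuple[EffectSize, ...]


@dataclass(frozen=True)
class FunnelData:
    """Per-study (effect, se) points and pseudo-CI contours for funnel plots."""

    points: pd.DataFrame
    contours: pd.DataFrame
    center: float


def egger_test(effects: Sequence[EffectSize]) -> EggerResult:
    """Egger's regression test of funnel-plot asymmetry.

    Regresses y_i/se_i on 1/se_i (OLS); the intercept estimates the
    small-study bias.  Requires k >= 3.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("Egger's test needs at least three effects")
    se = np.array([e.se for e in effects])
    y = np.array([e.value for e in effects])
    if np.allclose(se, se[0]):
        warnings.warn("all standard errors are equal: precision has no spread, "
                      "the Egger intercept is weakly identified", stacklevel=2)
    snd = y / se
    precision = 1.0 / se
    model = sm.OLS(snd, sm.add_constant(precision)).fit()
    return EggerResult(intercept=float(model.params[0]),
                       se_intercept=float(model.bse[0]), df=k - 2)


def _fixed_effect_center(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    return float(np.sum(w * y) / np.sum(w))


def _estimate_k0(y_centered: np.ndarray, estimator: str) -> float:
    """Estimate the suppressed-study count from centred effects.

    Assumes suppression on the LEFT (excess mass on the right); callers
    mirror the input to test the other side.  Ranks are of |y*| over all
    studies; T_n sums the ranks attached to positive y*.
    """
    n = len(y_centered)
    ranks = stats.rankdata(np.abs(y_centered))
    pos = y_centered > 0
    if estimator == "L0":
        t_n = float(np.sum(ranks[pos]))
        return (4.0 * t_n - n * (n + 1.0)) / (2.0 * n - 1.0)
    if estimator == "R0":
        # length of the run of largest ranks all belonging to positive effects
        order = np.argsort(ranks)
        gamma = 0
        for idx in order[::-1]:
            if pos[idx]:
                gamma += 1
            else:
                break
        return gamma - 1.0
    raise ValueError(f"unknown trim-and-fill estimator {estimator!r}")


def _trim_iterate(y: np.ndarray, v: np.ndarray, estimator: str,
                  max_iter: int = 20) -> int:
    """Iterated k0 estimation with fixed-effect trimming (left-suppression form)."""
    n = len(y)
    k0, prev = 0, -1
    history = [0]
    for _ in range(max_iter):
        keep = np.argsort(y)[: n - k0] if k0 > 0 else np.arange(n)
        center = _fixed_effect_center(y[keep], v[keep])
        est = _estimate_k0(y - center, estimator)
        new = int(max(0, round(est)))
        new = min(new, n - 2)  # keep at least two studies trimmed-in
        if new == k0:
            return k0
        prev, k0 = k0, new
        history.append(k0)
    raise RuntimeError(f"trim-and-fill did not converge; last k0 values "
                       f"{history[-2]} and {history[-1]}")


def trim_and_fill(
    effects: Sequence[EffectSize],
    side: Literal["auto", "left", "right"] = "auto",
    estimator: Literal["L0", "R0"] = "L0",
    method: Literal["DL", "REML"] = "REML",
) -> TrimFillResult:
    """Duval–Tweedie trim-and-fill adjustment for funnel asymmetry.

    ``side`` names the side of the funnel where studies are presumed missing;
    ``auto`` tries both and keeps the side with the larger estimated k0.
    Trimming uses fixed-effect centring; the final adjusted pooling of
    observed plus imputed mirror-image studies is random-effects.
    """
    if len(effects) < 3:
        raise ValueError("trim-and-fill needs at least three effects")
    y = np.array([e.value for e in effects])
    v = np.array([e.variance for e in effects])

    if side == "auto":
        k0_left = _trim_iterate(y, v, estimator)
        k0_right = _trim_iterate(-y, v, estimator)
        side = "left" if k0_left >= k0_right else "right"

    sign = 1.0 if side == "left" else -1.0
    ys = sign * y  # in this frame, suppression is on the left
    k0 = _trim_iterate(ys, v, estimator)

    if k0 == 0:
        return TrimFillResult(k0=0, side=side,
                              adjusted=pool_random_effects(effects, method),
                              estimator_tag=estimator, imputed=())

    n = len(y)
    trimmed_idx = np.argsort(ys)[n - k0:]           # most extreme on the excess side
    keep_idx = np.argsort(ys)[: n - k0]
    center = sign * _fixed_effect_center(ys[keep_idx], v[keep_idx])
    imputed = tuple(
        EffectSize(value=2.0 * center - effects[i].value,
                   variance=effects[i].variance,
                   study_id=f"fill:{effects[i].study_id}",
                   family_tag=effects[i].family_tag,
                   subgroup=effects[i].subgroup,
                   taxonomy_path=effects[i].taxonomy_path)
        for i in trimmed_idx
    )
    adjusted = pool_random_effects(list(effects) + list(imputed), method)
    return TrimFillResult(k0=k0, side=side, adjusted=adjusted,
                          estimator_tag=estimator, imputed=imputed)


def funnel_data(effects: Sequence[EffectSize], pooled: MetaResults) -> FunnelData:
    """Plot-ready funnel data: study points and pseudo-CI contours.

    Contours are the bands estimate ± z_level·se over the observed se range,
    at the 95%, 99% and 99.75% levels.
    """
    if len(effects) == 0:
        raise ValueError("no effects")
    points = pd.DataFrame(dict(
        study_id=[e.study_id for e in effects],
        value=[e.value for e in effects],
        se=[e.se for e in effects],
    ))
    se_max = max(points["se"].max(), 1e-12)
    se_grid = np.linspace(0.0, se_max * 1.05, 50)
    rows = []
    for level in FUNNEL_LEVELS:
        z = stats.norm.ppf(0.5 + level / 2.0)
        for s in se_grid:
            rows.append(dict(level=level, se=s,
                             lower=pooled.estimate - z * s,
                             upper=pooled.estimate + z * s))
    return FunnelData(points=points, contours=pd.DataFrame(rows),
                      center=pooled.estimate)
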