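"""Taxonomically structured meta-model for the temperature objective.

The model pools percent-change-per-°C effects while attributing between-study
variation to nested taxonomic levels::

    y_i = mu + u_order(i) + u_family(i) + u_species(i) + e_i,
    e_i ~ N(0, v_i)   with v_i the known sampling variance of effect i,
    u_level ~ N(0, sigma2_level)  (order effects optionally correlated by a
                                   tree-derived matrix C)

Two backends share this structure.  The MCMC backend is a conjugate Gibbs
sampler with weakly-informative inverse-gamma priors on each variance
component (V=1, nu=0.002 equivalent, i.e. shape = rate = 0.001) and a flat
prior on mu; the REML backend maximizes the restricted likelihood over the
three variance components and reports Wald-type intervals.  With all
taxonomic variances near zero both collapse to ordinary random-effects
pooling with tau² split across levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import Taxonomy
from .effects import EffectSize

__all__ = ["TaxonomicStructure", "MultilevelResults", "MultilevelMeta",
           "taxonomy_to_structure", "fit_multilevel"]

LEVELS = ("order", "family", "species")


@dataclass(frozen=True)
class TaxonomicStructure:
    """Incidence mappings from effects to order/family/species levels."""

    order_index: np.ndarray      # len k, codes into orders
    family_index: np.ndarray
    species_index: np.ndarray
    orders: tuple[str, ...]
    families: tuple[str, ...]    # order:family composite labels
    species: tuple[str, ...]     # order:family:species composite labels
    order_corr: np.ndarray       # q_o x q_o correlation matrix (identity if no tree)

    @property
    def n_orders(self) -> int:
        return len(self.orders)


def taxonomy_to_structure(
    taxonomy: Taxonomy | None,
    effects: Sequence[EffectSize],
) -> TaxonomicStructure:
    """Build the random-effect design structure from effect taxonomy paths.

    Family and species labels are nested within their parents (an identically
    named family in two orders is two distinct levels).  When a taxonomy with
    a branch-length tree is supplied, an order-level correlation matrix is
    derived from shared root-to-tip path lengths; otherwise orders are
    exchangeable (identity correlation).
    """
    paths = []
    for e in effects:
        if e.taxonomy_path is None or any(not str(x).strip() for x in e.taxonomy_path):
            raise ValueError(f"effect {e.study_id!r} lacks a full order/family/species path")
        p = tuple(str(x) for x in e.taxonomy_path)
        if taxonomy is not None:
            taxonomy.resolve(p)
        paths.append(p)
    orders = tuple(dict.fromkeys(p[0] for p in paths))
    families = tuple(dict.fromkeys(f"{p[0]}:{p[1]}" for p in paths))
    species = tuple(dict.fromkeys(f"{p[0]}:{p[1]}:{p[2]}" for p in paths))
    o_ix = np.array([orders.index(p[0]) for p in paths])
    f_ix = np.array([families.index(f"{p[0]}:{p[1]}") for p in paths])
    s_ix = np.array([species.index(f"{p[0]}:{p[1]}:{p[2]}") for p in paths])
    corr = taxonomy.order_correlation(list(orders)) if taxonomy is not None else np.eye(len(orders))
    return TaxonomicStructure(order_index=o_ix, family_index=f_ix,
                              species_index=s_ix, orders=orders,
                              families=families, species=species,
                              order_corr=corr)


@dataclass(frozen=True)
class MultilevelResults:
    """Overall mean with taxonomic variance components and per-order means."""

    mean: float
    se: float
    ci_half_width: float
    p: float
    var_components: dict[str, float]
    per_order_means: dict[str, tuple[float, float, float]]  # (mean, lo, hi)
    backend_tag: Literal["mcmc", "reml"]
    k: int
    posterior_mode: float | None = None
    mcmc_diagnostics: dict | None = None

    @property
    def ci(self) -> tuple[float, float]:
        return (self.mean - self.ci_half_width, self.mean + self.ci_half_width)

    def summary(self) -> str:
        lo, hi = self.ci
        lines = [
            f"Multilevel taxonomic meta-model ({self.backend_tag})",
            "=" * 48,
            f"k (effects)        {self.k:>12d}",
            f"overall mean       {self.mean:>12.4f}",
            f"95% interval       [{lo:.4f}, {hi:.4f}]",
            f"p (non-zero mean)  {self.p:>12.4g}",
            "variance components:",
        ]
        for name, val in self.var_components.items():
            lines.append(f"  {name:<10s}       {val:>12.4f}")
        lines.append("per-order means (95% interval):")
        for o, (m, l, h) in self.per_order_means.items():
            lines.append(f"  {o:<16s} {m:8.3f}  [{l:.3f}, {h:.3f}]")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return dict(mean=self.mean, se=self.se, ci_half_width=self.ci_half_width,
                    ci_low=self.ci[0], ci_high=self.ci[1], p=self.p,
                    var_components=dict(self.var_components),
                    per_order_means={k: list(v) for k, v in self.per_order_means.items()},
                    backend_tag=self.backend_tag, k=self.k,
                    posterior_mode=self.posterior_mode)


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive autocorrelation sum."""
    n = len(x)
    xc = x - x.mean()
    var = np.dot(xc, xc) / n
    if var == 0:
        return float(n)
    acf_sum = 0.0
    for lag in range(1, n):
        rho = np.dot(xc[:-lag], xc[lag:]) / ((n - lag) * var)
        if rho <= 0.0:
            break
        acf_sum += rho
    return float(n / (1.0 + 2.0 * acf_sum))


class MultilevelMeta:
    """Nested-random-effects meta-model over percent-per-°C effect sizes.

    Parameters
    ----------
    effects
        Effects with full order/family/species taxonomy paths and known
        sampling variances (entered as fixed measurement-error variances).
    taxonomy
        Optional :class:`~dgcmeta.data.Taxonomy`; supplies order-level
        correlation when its tree carries branch lengths.
    """

    def __init__(self, effects: Sequence[EffectSize], taxonomy: Taxonomy | None = None):
        if any(e.family_tag != "percent_per_degC" for e in effects):
            raise ValueError("multilevel model expects percent-per-°C effects")
        self.effects = list(effects)
        self.structure = taxonomy_to_structure(taxonomy, self.effects)
        if self.structure.n_orders < 2:
            raise ValueError("order variance unidentifiable with fewer than two orders")
        self.y = np.array([e.value for e in effects], dtype=float)
        self.v = np.array([e.variance for e in effects], dtype=float)

    @property
    def k(self) -> int:
        return len(self.y)

    # -- MCMC backend -----------------------------------------------------

    def fit(
        self,
        backend: Literal["mcmc", "reml"] = "mcmc",
        *,
        iterations: int = 13_000,
        burnin: int = 3_000,
        thin: int = 10,
        seed: int | None = None,
        prior_nu: float = 0.002,
        prior_V: float = 1.0,
    ) -> MultilevelResults:
        if backend == "mcmc":
            if seed is None:
                raise ValueError("the MCMC backend requires an explicit seed")
            return self._fit_mcmc(iterations, burnin, thin, seed, prior_nu, prior_V)
        if backend == "reml":
            return self._fit_reml()
        raise ValueError(f"unknown backend {backend!r}")

    def _fit_mcmc(self, iterations: int, burnin: int, thin: int, seed: int,
                  prior_nu: float, prior_V: float) -> MultilevelResults:
        rng = np.random.default_rng(seed)
        st = self.structure
        y, v = self.y, self.v
        k = self.k
        q_o, q_f, q_s = len(st.orders), len(st.families), len(st.species)
        a0 = prior_nu / 2.0
        b0 = prior_nu * prior_V / 2.0
        c_inv = np.linalg.inv(st.order_corr)
        identity_corr = np.allclose(st.order_corr, np.eye(q_o))

        inv_v = 1.0 / v
        sum_inv_v = inv_v.sum()
        # per-level precision accumulators: sum of 1/v_i within each group
        d_o = np.bincount(st.order_index, weights=inv_v, minlength=q_o)
        d_f = np.bincount(st.family_index, weights=inv_v, minlength=q_f)
        d_s = np.bincount(st.species_index, weights=inv_v, minlength=q_s)

        mu = float(np.sum(inv_v * y) / sum_inv_v)
        u_o = np.zeros(q_o)
        u_f = np.zeros(q_f)
        u_s = np.zeros(q_s)
        s2_o = s2_f = s2_s = 0.1

        n_keep = (iterations - burnin) // thin
        draws_mu = np.empty(n_keep)
        draws_s2 = np.empty((n_keep, 3))
        draws_uo = np.empty((n_keep, q_o))
        kept = 0

        for it in range(iterations):
            # mu | rest (flat prior)
            r = y - u_o[st.order_index] - u_f[st.family_index] - u_s[st.species_index]
            mu = rng.normal(np.sum(inv_v * r) / sum_inv_v, math.sqrt(1.0 / sum_inv_v))

            # order effects (possibly correlated prior)
            resid = y - mu - u_f[st.family_index] - u_s[st.species_index]
            b = np.bincount(st.order_index, weights=inv_v * resid, minlength=q_o)
            if identity_corr:
                prec = 1.0 / s2_o + d_o
                u_o = rng.normal(b / prec, np.sqrt(1.0 / prec))
            else:
                q_mat = c_inv / s2_o + np.diag(d_o)
                chol = np.linalg.cholesky(q_mat)
                m = np.linalg.solve(q_mat, b)
                z = rng.standard_normal(q_o)
                u_o = m + np.linalg.solve(chol.T, z)

            # family effects
            resid = y - mu - u_o[st.order_index] - u_s[st.species_index]
            b = np.bincount(st.family_index, weights=inv_v * resid, minlength=q_f)
            prec = 1.0 / s2_f + d_f
            u_f = rng.normal(b / prec, np.sqrt(1.0 / prec))

            # species effects
            resid = y - mu - u_o[st.order_index] - u_f[st.family_index]
            b = np.bincount(st.species_index, weights=inv_v * resid, minlength=q_s)
            prec = 1.0 / s2_s + d_s
            u_s = rng.normal(b / prec, np.sqrt(1.0 / prec))

            # variance components | u  (inverse-gamma conjugate updates)
            quad_o = u_o @ c_inv @ u_o if not identity_corr else np.dot(u_o, u_o)
            s2_o = 1.0 / rng.gamma(a0 + q_o / 2.0, 1.0 / (b0 + quad_o / 2.0))
            s2_f = 1.0 / rng.gamma(a0 + q_f / 2.0, 1.0 / (b0 + np.dot(u_f, u_f) / 2.0))
            s2_s = 1.0 / rng.gamma(a0 + q_s / 2.0, 1.0 / (b0 + np.dot(u_s, u_s) / 2.0))

            if it >= burnin and (it - burnin) % thin == 0:
                draws_mu[kept] = mu
                draws_s2[kept] = (s2_o, s2_f, s2_s)
                draws_uo[kept] = u_o
                kept += 1

        draws_mu = draws_mu[:kept]
        draws_s2 = draws_s2[:kept]
        draws_uo = draws_uo[:kept]

        post_mean = float(draws_mu.mean())
        lo, hi = np.quantile(draws_mu, [0.025, 0.975])
        half = float((hi - lo) / 2.0)
        center = float((hi + lo) / 2.0)
        # pMCMC convention: twice the smaller posterior tail, floored at 2/n
        p_gt = float(np.mean(draws_mu > 0))
        p = max(2.0 * min(p_gt, 1.0 - p_gt), 2.0 / kept)
        # posterior mode from a histogram of the mean draws
        hist, edges = np.histogram(draws_mu, bins=min(50, max(10, kept // 20)))
        mode = float((edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2.0)

        per_order = {}
        for j, o in enumerate(st.orders):
            om = draws_mu + draws_uo[:, j]
            ql, qh = np.quantile(om, [0.025, 0.975])
            per_order[o] = (float(om.mean()), float(ql), float(qh))

        resid_draws = None
        diagnostics = dict(
            ess_mean=_ess(draws_mu),
            ess_var_components={name: _ess(draws_s2[:, i])
                                for i, name in enumerate(LEVELS)},
            iterations=iterations, burnin=burnin, thin=thin, seed=seed,
            n_draws=kept, prior_nu=prior_nu, prior_V=prior_V,
        )
        return MultilevelResults(
            mean=post_mean, se=float(draws_mu.std(ddof=1)),
            ci_half_width=half, p=p,
            var_components={"order": float(draws_s2[:, 0].mean()),
                            "family": float(draws_s2[:, 1].mean()),
                            "species": float(draws_s2[:, 2].mean())},
            per_order_means=per_order, backend_tag="mcmc", k=self.k,
            posterior_mode=mode, mcmc_diagnostics=diagnostics,
        )

    # -- REML backend ------------------------------------------------------

    def _marginal_cov(self, s2: np.ndarray) -> np.ndarray:
        st = self.structure
        k = self.k
        cov = np.diag(self.v).astype(float)
        zo = np.zeros((k, len(st.orders)))
        zo[np.arange(k), st.order_index] = 1.0
        cov += s2[0] * zo @ st.order_corr @ zo.T
        same_f = st.family_index[:, None] == st.family_index[None, :]
        same_s = st.species_index[:, None] == st.species_index[None, :]
        cov += s2[1] * same_f + s2[2] * same_s
        return cov

    def _neg2_reml(self, log_s2: np.ndarray) -> float:
        s2 = np.exp(log_s2)
        vmat = self._marginal_cov(s2)
        try:
            chol = np.linalg.cholesky(vmat)
        except np.linalg.LinAlgError:
            return 1e12
        one = np.ones(self.k)
        vinv_y = np.linalg.solve(vmat, self.y)
        vinv_1 = np.linalg.solve(vmat, one)
        denom = one @ vinv_1
        mu = (one @ vinv_y) / denom
        r = self.y - mu
        quad = r @ np.linalg.solve(vmat, r)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return float(logdet + math.log(denom) + quad)

    def _fit_reml(self) -> MultilevelResults:
        x0s = [np.log([0.5, 0.5, 0.5]), np.log([2.0, 0.1, 0.1]),
               np.full(3, -6.0)]
        best = None
        for x0 in x0s:
            res = optimize.minimize(self._neg2_reml, x0, method="Nelder-Mead",
                                    options=dict(xatol=1e-6, fatol=1e-8,
                                                 maxiter=2000))
            if best is None or res.fun < best.fun:
                best = res
        s2 = np.exp(best.x)
        s2[s2 < 1e-8] = 0.0
        vmat = self._marginal_cov(s2)
        one = np.ones(self.k)
        vinv_1 = np.linalg.solve(vmat, one)
        denom = float(one @ vinv_1)
        mu = float((one @ np.linalg.solve(vmat, self.y)) / denom)
        se = math.sqrt(1.0 / denom)
        z = mu / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        half = 1.959963984540054 * se
        r = self.y - mu
        vinv_r = np.linalg.solve(vmat, r)

        st = self.structure
        per_order = {}
        for j, o in enumerate(st.orders):
            zo_col = (st.order_index == j).astype(float)
            # BLUP of the order deviation and its approximate conditional variance
            c_row = s2[0] * st.order_corr[j]  # cov(u_j, u)  (q_o,)
            zo = np.zeros((self.k, len(st.orders)))
            zo[np.arange(self.k), st.order_index] = 1.0
            cov_uj_y = zo @ c_row          # cov(u_j, y)  (k,)
            blup = float(cov_uj_y @ vinv_r)
            cond_var = float(s2[0] - cov_uj_y @ np.linalg.solve(vmat, cov_uj_y))
            var_total = max(cond_var, 0.0) + se**2
            m = mu + blup
            hw = 1.959963984540054 * math.sqrt(var_total)
            per_order[o] = (m, m - hw, m + hw)

        return MultilevelResults(
            mean=mu, se=se, ci_half_width=half, p=p,
            var_components={"order": float(s2[0]), "family": float(s2[1]),
                            "species": float(s2[2])},
            per_order_means=per_order, backend_tag="reml", k=self.k,
        )

    def variance_components_frame(self, results: MultilevelResults) -> pd.DataFrame:
        """Export variance components as a delimited-ready table."""
        return pd.DataFrame(
            [dict(component=name, variance=val, backend=results.backend_tag)
             for name, val in results.var_components.items()])


def fit_multilevel(
    effects: Sequence[EffectSize],
    taxonomy: Taxonomy | None = None,
    backend: Literal["mcmc", "reml"] = "mcmc",
    **chain,
) -> MultilevelResults:
    """Functional wrapper: build the model and fit with the chosen backend."""
    return MultilevelMeta(effects, taxonomy).fit(backend, **chain)
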