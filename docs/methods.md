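# Methods

This document records the statistical models implemented in `dgcmeta`, the
default parameter choices and why they were made, what the synthetic
generators do and do not cover, and known limitations. Notation: `k` effects
`y_i` with known sampling variances `v_i`.

## 1. Unit conversion and error propagation

Respirometry studies report metabolic rate in incompatible conventions.
`convert_rate_units` converts a whole-animal rate to a mass-specific rate by
dividing two summarized arms, propagating uncertainty with the first-order
Taylor (delta-method) expansion of a ratio of independent normals:

```
SD(A/B) = (A/B) * sqrt(V_A / A² + V_B / B²)
```

where `V_A`, `V_B` are the variances of the numerator and denominator means.
Both variances appear with their own quantity; the expansion is first-order,
so each term uses the matching arm's variance.

**Accuracy envelope.** The first-order expansion tracks the true
Monte-Carlo SD of the ratio to within 5% when the *denominator* coefficient
of variation is ≤ 0.1 (numerator CV up to 0.2 is unproblematic). At
denominator CV ≈ 0.2 the true SD is roughly 20–25% larger than the Taylor
value, because the near-zero tail of the denominator fattens the ratio
distribution. The tests pin the 5% agreement inside the validated envelope;
users converting arms with denominator CV > 0.1 should treat the propagated
SD as a lower bound.

Water-loss conversions (`convert_water_loss_units`) are exact scalings
(µg/h × 10⁻³, mg/min × 60 → mg/h).

## 2. Effect sizes

### 2.1 Hedges' g (two-arm objectives)

Standardized mean difference with the small-sample correction

```
J = 1 − 3 / (4(n1 + n2 − 2) − 1)
g = J * (m2 − m1) / s_pooled
Var(g) = (n1 + n2) / (n1 n2) + g² / (2 (n1 + n2))
```

Direction is explicit: `comparison_minus_reference` for every objective, so
negative hygric g means less water loss during DGC. A small-sample variance
variant (J² applied to the d-based variance) is available behind a flag but
is not the default, matching the common large-sample form.

### 2.2 Log-linear temperature slope

For a study reporting mean rates at m temperatures, the slope of
`ln(rate)` on temperature is fit by n-weighted least squares. Its sampling
variance pools two components:

- within-temperature variation on the log scale, `σ₁² = Σ (n_j − 1) σ_LM,j²`,
  with `σ_LM = SD / mean` (delta method for the SD of a log);
- lack-of-fit, `σ₂² = Σ n_j (ln R_j − ln f_j)²` against the fitted line.

```
SE(β₁)² = ((σ₁² + σ₂²) / (Σn − 2)) / Σ n_j (x_j − x̄)²,   x̄ = Σ n_j x_j / Σ n_j
```

The slope converts to the meta-analytic scale as a percent change per °C:

```
ES = (e^β₁ − 1) × 100,    Var(ES) = 100² e^{2β₁} SE(β₁)²
```

and a pooled percent converts to the conventional thermal-sensitivity
coefficient as `Q10 = (1 + pct/100)^10`. Note that some published syntheses
print Q10 values inconsistent with this identity (e.g. 8.13 %/°C reported
alongside Q10 ≈ 2.0, where the identity gives 2.19); `dgcmeta` applies the
standard formula throughout.

## 3. Random-effects pooling

Inverse-variance random-effects model with weights `w_i = 1/(v_i + τ²)`.

- **DerSimonian–Laird**: `τ² = max(0, (Q − df)/C)`, `C = Σw − Σw²/Σw` on
  fixed-effect weights — closed form, used for quick checks.
- **REML** (default): fixed-point iteration
  `τ²_new = Σ w_i²((y_i − μ̂)² − v_i) / Σ w_i² + 1/Σ w_i`, tolerance 1e-8,
  max 100 iterations, DL fallback with a warning on non-convergence. REML is
  the default because DL is known to underestimate τ² under high
  heterogeneity, which is exactly the regime of the hygric objective.

`I² = max(0, (Q − df)/Q) × 100`. Confidence intervals use the normal
quantile (±1.96 SE); the Knapp–Hartung adjustment is not applied, matching
the classical Wald summary most older meta-analyses report. A single effect
passes through with its own variance and a warning.

**Outlier rule.** Leave-one-out externally standardized residuals:
`z_i = (y_i − μ̂₋ᵢ) / sqrt(v_i + τ²₋ᵢ + SE(μ̂₋ᵢ)²)`, flag at `|z| > 1.96`
(configurable), re-pool without flagged effects. At this threshold a fully
homogeneous set of ~20 effects still flags at least one residual in roughly
two thirds of realizations — the rule is a screening device, not a test, and
results are always reported alongside the unfiltered pool.

## 4. Publication-bias diagnostics

- **Egger regression**: regress `y_i / se_i` on `1 / se_i`; the intercept is
  the asymmetry coefficient, tested with a t statistic on k − 2 df. This
  precision-form is algebraically the weighted regression of `y` on `se` and
  matches standard linear-model output exactly. Under a symmetric null with
  independent `y` and `se` the test is exactly calibrated (the suite checks
  a 5% ± 2-point rejection rate over 2,000 replicates). For standardized
  mean differences the `g²` term in `Var(g)` couples effect and precision,
  so large true effects produce nonzero intercepts without any censoring —
  interpret Egger p-values for SMDs with that in mind.
- **Trim-and-fill** (Duval–Tweedie): `L0 = (4 T_n − n(n+1)) / (2n − 1)` with
  `T_n` the rank sum of effects above the center, iterated with
  *fixed-effect* trimming; the final adjusted pool is random-effects over
  observed plus mirrored imputed effects. `R0` is available as an
  alternative estimator; `side="auto"` tests both sides and adjusts the one
  with the larger estimated `k0`. Fixed-effect trimming was chosen because
  τ² re-estimated on a trimmed, asymmetric subset is unstable; the reference
  implementation agrees with this configuration to ~1e-8.
  A note on expectations: for an exactly mirrored-pair funnel, deleting d
  studies from one side is *not* generally recovered as `k0 = d` — the rank
  arithmetic caps the iterated L0 below d for small k. Recovery holds for
  generic (non-degenerate) symmetric configurations, which is what the test
  fixture uses.
- **Funnel data**: points plus pseudo-confidence contours at 0.95 / 0.99 /
  0.9975 for plotting in any frontend (the package emits tables, not
  figures).

## 5. Taxonomic multilevel model

Species are not independent replicates, so the temperature objective fits

```
y_i = μ + u_order(i) + u_family(i) + u_species(i) + e_i
u_level ~ N(0, σ²_level),   e_i ~ N(0, v_i)  with v_i known
```

with family labels nested inside orders and species inside families
(composite labels prevent accidental pooling of same-named families across
orders).

**MCMC backend (default).** All conditionals are conjugate (normal mean
updates, inverse-gamma variance updates with prior ν = 0.002, V = 1 — a
near-flat prior on each σ²; flat prior on μ), so the sampler is a plain
Gibbs scheme. Defaults: 13,000 iterations, 3,000 burn-in, thinning 10
(1,000 retained draws). A seed is mandatory and the chain is bit-reproducible
for a given seed. Reported: posterior mean and SE of μ, central 95%
interval, `pMCMC = 2 × min(tail)` floored at `2/n_draws`, posterior means of
the variance components, per-order means with intervals (BLUP-like posterior
summaries), and effective sample sizes from the autocorrelation of the
retained draws.

**REML backend (cross-check).** The same likelihood maximized over
`log σ²` by Nelder–Mead from three starts, with GLS for μ and BLUPs for
per-order means. No installed Python mixed-model package fits this model
with fixed per-row residual variances, so this backend is implemented
directly (Cholesky-based REML objective). The two backends agree on the
posterior/REML mean to well under 0.5 percentage points in well-identified
simulations, and both collapse to the simple random-effects pool when the
taxonomic variances are zero.

**Phylogeny.** The default treats orders as exchangeable (identity
correlation). An ultrametric Newick tree can supply an order-level
correlation matrix (shared root-path depth over total depth); this is
optional because published order-level topologies often lack branch lengths,
and inventing them would add false precision.

## 6. Synthetic generators

All generators take a frozen `SimulationConfig` with a mandatory seed; the
defaults *are* the study conditions and were fixed before any acceptance
runs.

- **Two-arm** (`simulate_two_arm_studies`): per-study true effects
  `θ_i ~ N(μ, τ²)`; arm means normal around baseline and
  baseline + θ·SD; arm SDs drawn so the squared SDs follow their χ²
  sampling law, keeping Hedges' g unbiased in closed loop.
- **Temperature series** (`simulate_temperature_series`): per-individual
  lognormal rates at each temperature, per-study slope
  `β₁ + (u_order + u_family + u_species + study deviation)/100` (taxonomic
  deviations live on the percent scale), m = 3–6 temperatures in 10–35 °C,
  baseline 0.5 ml g⁻¹ h⁻¹ at 25 °C. An additive-noise variant exists for
  diagnostics.
- **Taxonomic effects** (`simulate_taxonomic_effects`): effects drawn
  directly from the multilevel model above, for estimator-level checks.
- **Censoring** (`apply_publication_censoring`): one-sided-p threshold
  suppression with configurable severity, used to verify that Egger moves in
  the favored direction under planted bias.

Default study conditions per objective (chosen once, to emulate typical
published syntheses of this literature): hygric — 42 effects, 3 orders,
true g −3.27, τ² = 4 (≈ 90% I²); hyperoxia — 29 effects, 4 orders, true g
0.21, τ² = 0; hypoxia — 29 effects, 4 orders, true g 0.27, τ² = 0.045
(≈ 20% I²); temperature — 30 studies, 9 orders, true slope
β₁ = ln(1.0813) (8.13 %/°C), order/family/species variances 4/1/1 on the
percent scale.

## 7. Numerical and design choices

- Library code is used where it is the standard tool (pandas for delimited
  IO, statsmodels OLS inside Egger, dendropy for Newick, scipy for
  distributions and optimization); the meta-analytic machinery itself
  (effect sizes, τ² estimators, trim-and-fill, Gibbs sampler, REML
  objective) is implemented in this package because its exact conventions
  are the subject under test.
- DL, REML, Egger, and trim-and-fill were validated once against an
  independent reference implementation on frozen fixtures; the reference
  values are hard-coded in the test suite so tests run offline and fast.
- Acceptance-scale simulation sizes (e.g. 200 pooling replicates at k = 200,
  120 closed-loop multilevel replicates at reduced chain length, 2,000 Egger
  null replicates) were sized to give Monte-Carlo standard errors well below
  the tolerances being checked while keeping the suite fast.

## 8. Limitations

- Taylor-propagated ratio SDs are only validated to 5% for denominator
  CV ≤ 0.1 (see §1).
- CIs are Wald-type; no Knapp–Hartung, no prediction intervals.
- The multilevel model assumes known `v_i` and normal random effects; the
  inverse-gamma prior, though near-flat, can matter when a variance
  component is weakly identified (few orders or few effects per order).
- Trim-and-fill `k0` recovery is configuration-dependent for small k
  (see §4); the method is a sensitivity analysis, not an estimator of the
  number of missing studies.
- The generators model summary-level reporting only; they do not simulate
  raw respirometry traces, measurement drift, or correlated multi-effect
  studies (each effect is one independent study record).
- No empirical dataset ships with the package; all worked numbers are from
  the seeded synthetic loop. Applying the pipeline to extracted literature
  tables requires the user to supply them in the documented schema.
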