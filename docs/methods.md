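# Methods

`rdhealth` implements an individual-level analysis of how income inequality
relates to physical and mental health, with social capital as the mediating
channel, on respondent-level survey microdata of the CFPS (China Family
Panel Studies) type. This note documents the statistical models, the
numerical choices, the synthetic-data generator that stands in for the
restricted survey files, and the limits of what the test suite shows.

## Relative deprivation as the exposure

Income inequality is measured at the individual level by the Kakwani
relative-deprivation index. For a reference group with incomes
`I_1..I_n`, mean `μ`, the score of person `i` is

    KI_i = (1 / (n μ)) Σ_{j : I_j > I_i} (I_j − I_i)
         = γ⁺_i (μ⁺_i − I_i) / μ,

where `γ⁺_i` is the share of the group strictly richer than `i` and `μ⁺_i`
their mean income. Conventions:

- **Ties.** "Richer" is strict (`>`), so tied incomes share one score, the
  maximum-income individual(s) score exactly 0, and the two algebraic forms
  above remain equal under ties. Scores lie in `[0, 1)` and are
  non-increasing in income rank.
- **Identity.** The group mean of the Kakwani scores equals the group's
  Gini coefficient analytically; the test suite uses this as its primary
  oracle (tolerance 1e-10) together with agreement of the two algebraic
  forms (1e-12).
- **Variants.** The Yitzhaki index is the unnormalized sum
  (`KI × μ`, currency units, 1-homogeneous in income); the Podder index
  replaces income differences by log-income differences,
  `(1/n) Σ_{j: I_j > I_i} (ln I_j − ln I_i)`, and is invariant to income
  rescaling. The log-ratio form is our reading of Podder's measure; it is a
  design choice, exposed here because other readings exist.
- **Reference groups.** `group_deprivation` recomputes any index within
  subgroups (gender, urban/rural, region): the subgroup's own income vector
  becomes the comparison set, which is also what the subgroup heterogeneity
  driver does by default before refitting.
- Zero or negative incomes are rejected, not clamped: the log-based index
  is undefined there, and survey cleaning is expected to have dropped
  invalid records upstream.

Computation is `O(n log n)` via suffix sums over unique income values, and
scores are attached to rows, not ranks, so results are order-independent.

## Ordered-logit health models

Both health outcomes are ordinal (mental health 1–5, physical health 1–4)
and are modelled by ordered logistic regression: a latent
`y* = x'β + ε` with standard-logistic `ε`, cut at thresholds
`r_1 < … < r_{K−1}`, so `P(y = k) = F(r_k − x'β) − F(r_{k−1} − x'β)`.

- **Identification**: no intercept, free cutpoints (the cutpoints carry
  location) — the Stata `ologit` convention, so coefficients are
  comparable across refits and odds ratios are `exp(β)`.
- **Estimation**: analytic-gradient maximum likelihood. An L-BFGS pass in
  an unconstrained parameterization (first cutpoint plus log-spacings,
  which enforces the ordering) is followed by damped Newton polishing in
  the natural `(β, r)` space until the score's infinity norm is ≤ 1e-6
  (default; max 500 L-BFGS iterations, 50 Newton steps). Cutpoints are
  initialized at the empirical logits of the cumulative category
  frequencies, slopes at zero. The Newton line search accepts a step when
  the objective does not increase beyond rounding noise at the
  likelihood's own scale (`1e-10·(1+|ℓ|)`) or when the score norm falls;
  a fixed `1e-12` slack is meaningless at `|ℓ| ≈ 2e4`.
- **Likelihood numerics**: `log[F(u) − F(l)]` is computed as
  `log_expit(u) + log_expit(−l) + log(−expm1(l − u))`, which is free of
  catastrophic cancellation in both tails.
- **Covariance**: inverse observed information (numerical Hessian of the
  analytic gradient, central differences), or the Huber–White sandwich
  `H⁻¹(S'S)H⁻¹` from analytic per-observation scores when robust errors
  are requested. No clustering.
- **Degenerate inputs**: a one-category outcome, zero-variance predictors,
  and under-identified designs raise immediately; a coefficient passing
  |β| > 30 during polishing raises a separation error (at that magnitude a
  unit predictor change moves the odds by e³⁰ — the MLE is diverging).
- **Fit statistics**: McFadden's pseudo-R², `1 − ℓ_full/ℓ_null`, with the
  null (cutpoints-only) log-likelihood available in closed form
  `Σ_k n_k log(n_k/n)`.
- Province fixed effects enter as indicator contrasts, first level as
  reference. An individual random effect is not separately identified in a
  single cross-section and is absorbed into the logistic error; this
  attenuates coefficients by the usual variance-inflation factor
  `sqrt(σ²_logistic / (σ²_logistic + σ²_prov))` when the province terms
  are *omitted* (≈1.4% at the generator defaults), which the recovery
  tests account for by fitting at realistic n with a ±0.1 band.

The fitter is cross-checked two ways: against an independently coded IRLS
binary logit (the 2-category reduction must agree to 1e-6) and against
statsmodels' `OrderedModel` on multi-category data. statsmodels is not used
as the backend because the pipeline needs sandwich covariances over
`(β, cutpoints)`, tighter score tolerances than its BFGS achieves, and
analytic-gradient speed for the resampling-heavy stages.

Collinearity diagnostics (`vif_tolerance`) report `VIF_k = 1/(1 − R²_k)`
from regressing each predictor on the others with intercept, and
`tolerance = 1/VIF`; exact collinearity is reported as an infinite VIF with
a flag rather than an exception, since the screen's job is to show it.

## KHB mediation decomposition

Coefficients of nested nonlinear models are not comparable: adding a
mediator rescales the latent variable. The KHB device makes them
comparable by conditioning both models on the same information:

1. regress the mediator on exposure and covariates (OLS); keep slope `b`
   and the residual `ẽ`;
2. **reduced model**: outcome ~ exposure + `ẽ` + covariates (ordered
   logit) → total effect TE;
3. **full model**: outcome ~ exposure + mediator + covariates → direct
   effect DE and mediator coefficient `c`;
4. IE = TE − DE, mediation percentage `100·IE/TE`.

Because the reduced and full designs span the same column space, the two
fits have identical likelihood optima and IE equals `b·c` *exactly*, in the
linear family and in the logit family alike; the tests assert both (1e-8).
Two further consequences used as invariants: rescaling the mediator leaves
TE, DE, IE unchanged (the residualization absorbs scale), and IE ≡ TE − DE
holds by construction, not approximately.

Mediators are decomposed one at a time (the reported layout); joint
decomposition is deliberately not a default because mediator ordering and
mutual confounding among the social-capital measures is unresolved.

**Uncertainty.** Default: nonparametric bootstrap (200 replicates,
resampling rows and refitting the whole decomposition; deterministic given
a seed; minimum 50 replicates). The cheap alternative filled in at
decomposition time is a delta method for IE = `b·c` using Goodman's
unbiased product-variance `c²V(b) + b²V(c) − V(b)V(c)` (falling back to
the plug-in Sobel form if the correction makes the estimate nonpositive).
The unbiased form matters under the null `b = 0`: the plug-in `b̂²`
inflates the variance and makes the z-test conservative, while the Goodman
form is calibrated — in the package's own 500-replicate null simulation
(n = 2,000 per replicate) the 5%-level rejection rate is 4.2%, inside the
binomial band around nominal. TE and DE standard errors come from the
respective fits' sandwich covariances. p-values use the standard normal
reference, two-sided.

## Robustness battery and subgroups

Five variants, each a refit reported side by side: swap the outcome for
self-rated health; replace the Kakwani exposure with the Yitzhaki index on
log income, or with the Podder index; winsorize the income tails at 1% and
recompute the exposure; convert the outcome to a numeric scale and fit OLS
(HC1 errors).

**Winsorization convention.** Order-statistic replacement: the
`floor(n·f)` smallest values are set equal to the next order statistic,
symmetrically at the top (scipy's `mstats.winsorize` semantics). This
convention — rather than clipping at interpolated quantiles — is chosen
because it is idempotent, which a resampling-free robustness check should
be; e.g. `[1,2,3,4]` at `f = 0.25` becomes `[2,2,3,3]`. A trimming mode
(dropping the tail rows instead) is also provided, since published sample
counts after "1% tail treatment" often reveal trimming rather than
winsorizing; winsorizing is the default.

Subgroup runs split by gender, household registration (urban/rural) or
region, re-reference the deprivation index within each stratum by default
(switchable), skip strata whose outcome collapses to a single category
with a warning, and partition the sample exactly.

## Synthetic data generator

The generator exists so that every downstream stage is testable without
the restricted survey files. It emulates the analysis table's structure
and the planted causal structure the methods are meant to recover — not
the survey's sampling design.

- **Income**: log-normal, `σ_log = 0.972` by default, implying a
  population Gini of `2Φ(σ/√2) − 1 ≈ 0.508`, the national level the
  survey reports; mean log-income 9.8 (≈ 18k yuan per capita).
- **Deprivation**: the Kakwani index is computed within the generated
  sample itself, exactly as the analysis will compute it.
- **Mediators** (trust, fairness, support, relations, network density):
  `m_k = mean_k + b_k(KI − mean KI) + Gaussian noise`, with target
  means/SDs set to the survey's published marginals, then clipped to their
  admissible ranges (relations rounded to its 0–10 scale). Default
  `b_k < 0`: deprivation erodes social capital.
- **Latent health**: `a(KI − mean KI) + Σ c_k(m_k − mean_k) +
  γ'(x − mean x) + province effect + logistic noise`, discretized through
  fixed cutpoints into the 5-level mental and 4-level physical outcomes
  (plus an independent-noise self-rated outcome for the swap variant).
  Defaults `a = −0.9`, cognitive `c > 0`, small positive structural `c`.
  Centring anchors the latent scale at zero so the cutpoint defaults
  directly set the marginal category frequencies; they were chosen once so
  the outcome means/SDs sit near the published 4.24/0.82 and 3.38/0.85.
- **Covariates**: drawn to match the published means/SDs (urban share
  0.493, mean age 47.8, education 7.3 years, …); effects `γ` default to
  magnitudes of the published covariate coefficients. Both logistic noises
  (mental/physical) share one systematic component.
- **Geography**: provinces uniform over `n_provinces` (default 31) with
  Gaussian province effects (sd 0.3); region is a deterministic function
  of province index, ~45% east / 25% central / 30% west.
- Determinism: one `numpy` `default_rng(seed)` drives everything; the
  same config yields bit-identical tables.

**What passing tests do and do not show.** The generator draws covariates
independently of income and of each other, has no missingness, no
measurement error in the mediators beyond clipping, a single shared latent
for both outcomes, and exactly the linear-in-index structure the models
assume. Recovery and calibration results on these tables therefore
validate the *estimators and their implementation* — they say nothing
about unmeasured confounding, reverse causality, or misspecification in
real survey data, which the cross-sectional design cannot rule out.

## Problem sizes and determinism

Test problem sizes are chosen as the smallest that make each check sharp:
hand-checkable vectors for the index algebra; n = 200 × 50 datasets for
the binary-oracle equivalence; n = 2,000 × 500 replicates for the null
calibration of the mediation z-test; n = 20,000 × 20 seeds for sign and
magnitude recovery at survey scale. The acceptance script runs the full
pipeline at the survey's N = 22,751. All randomness flows from explicit
seeds; pipeline artifacts are reproducible byte for byte given the same
configuration and seed.

## Known limitations

- One mediator per decomposition; no exposure–mediator interaction, no
  counterfactual (causal-mediation) estimands, no sensitivity analysis.
- No survey weights, no clustering of standard errors, no multilevel
  random effects.
- Proportional odds is assumed, not tested.
- The Podder index formula is our log-ratio reading (see above).
- The delta-method IE variance treats `b̂` and `ĉ` as independent; the
  bootstrap does not need that assumption and is the default for reported
  tables.
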