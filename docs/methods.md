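# Methods

This note documents the statistical model behind `vitdmr`, the conventions
chosen where more than one is defensible, what the synthetic-data generator
does and does not emulate, and the problem sizes used by the test suite.

## Design

Two arms estimate the causal effect of circulating 25-hydroxyvitamin D
(25-OHD, log-transformed nmol/L) on colorectal cancer (CRC) risk from a
six-variant genetic instrument:

1. **Summary-statistics two-sample MR.** Per-variant effects on the exposure
   (`X_k`, SE `σ_xk`) come from an external exposure GWAS; effects on the
   outcome (`Y_k`, SE `σ_yk`) from a CRC GWAS meta-analysis in independent
   samples. Estimators combine the per-variant Wald ratios `Y_k / X_k`.
2. **Individual-level MR.** A per-individual genetic risk score (GRS) —
   allele counts weighted by the external exposure effect sizes — is the
   single instrument. Stage 1 (linear): measured log 25-OHD on the GRS in the
   exposure subsample. Stage 2 (logistic): case status on the GRS in each
   case–control cohort. The causal log-OR is `β2/β1`, pooled across cohorts
   by random-effects meta-analysis.

Variants are assumed independent (no LD) and harmonized so every
`X_k > 0` (all effects oriented to the 25-OHD-raising allele); the package
refuses Egger fits on unharmonized input because the Egger slope is not
orientation-invariant.

## Conventions and numerical choices

- **Wald-ratio SE**: first-order delta `σ_yk / |X_k|`, ignoring
  exposure-side uncertainty, matching the IVW SE formula
  `√(1/Σ X_k² σ_yk⁻²)` which involves only outcome variances.
- **Egger residual scale**: SEs use a multiplicative overdispersion
  parameter floored at 1 (`max(1, Q_egger/(k−2))`), the convention of the
  standard summary-MR software; switchable via `overdispersion_floor=False`.
- **Median estimators**: weights normalized to sum 1; percentile position of
  the j-th sorted ratio is `cumsum_j − w_j/2`; linear interpolation at 0.5.
  SEs from a parametric bootstrap (default 10,000 draws of each ratio from
  `Normal(ratio_k, se_k)`); draws are keyed to variants in `variant_id`
  order so results are invariant to input row order. A seed is mandatory.
- **Penalization**: weight multiplier `min(1, 20·p_k)` where `p_k` is the
  upper-tail χ²₁ probability of the variant's heterogeneity contribution
  around the unpenalized estimate of the same method. Homogeneous variants
  keep full weight, so well-behaved instruments leave estimates unchanged.
- **Robust fits**: the weighted regression is transformed to homoskedastic
  form and refit by iteratively reweighted M-estimation with Tukey's
  biweight (95%-efficiency constant c = 4.685, tolerance 1e-8, ≤ 200
  iterations), seeded from the least-squares solution (statsmodels RLM).
  This is an M-type approximation to a full S+MM robust fit; on outlier-free
  instruments the two agree closely, and the package documents results from
  this convention only.
- **Taylor SE of the two-stage ratio**: both variance terms,
  `se² = se2²/β1² + β2²·se1²/β1⁴`, no covariance term (the two stages come
  from non-overlapping samples), no higher-order terms.
- **Stage-1 sharing**: `β1` is estimated once in the designated exposure
  subsample and reused for every cohort's ratio — the study design has
  measured 25-OHD in a single control series — with its uncertainty entering
  each cohort's SE. By default the stage-1 adjustment set matches stage 2;
  a mismatch is permitted but logged.
- **Meta-analysis**: DerSimonian–Laird specifically. Fixed weights
  `1/se_i²` give Cochran's Q; `τ² = max(0,(Q−(m−1))/(Σu−Σu²/Σu))`; pooled
  estimate with weights `1/(se_i²+τ²)`. Heterogeneity flagged at
  p < 0.10; causal estimates tested two-sided at α = 0.05; all 95% CIs use
  the normal 1.96 multiplier.
- **Missing data**: missing dosages are mean-imputed per variant within
  cohort (counts logged); individuals missing a covariate used in a model
  are dropped complete-case (logged). Covariate adjustment is per-cohort,
  by availability.
- **Degenerate inputs**: zero `beta_exposure` rows are dropped at
  harmonization (orientation undefined); a perfect stage-1 fit (R² = 1) and
  stage-2 separation raise errors rather than returning unusable estimates.

## Power

The analytic power function uses the normal-approximation method for
binary-outcome MR: with total n, case fraction K, instrument R² and
hypothesized OR per exposure SD, the attenuated linear-scale effect
`b = K(OR/(1+K(OR−1))−1)` with variance `(K(1−K)−b²)/(n·R²)` yields
`NCP = b²/v` and two-sided power `Φ(√NCP−z) + Φ(−√NCP−z)`. The two-sided
form makes power → α as OR → 1. The linearization is not exactly symmetric
in OR ↔ 1/OR and is mildly conservative for ORs far from 1; the simulation
cross-check in the test suite therefore uses a modest effect (OR 0.85/SD,
the regime this method is used for), where simulated two-stage rejection
rates agree with the formula within Monte-Carlo error.

## Synthetic cohorts

The generator draws, per individual: six independent biallelic genotypes in
Hardy–Weinberg proportions; a latent standard-normal confounder `U`;
exposure `= μ + Σ β_k (g_k − 2p_k) + γU + ε` with the per-allele effects
rescaled so the instrument explains exactly the target R² (default 0.0284)
and `Var(ε)` solved from the variance decomposition (an infeasible target
R² raises an error reporting the analytic maximum `1 − γ²/σ²`); and a
logistic outcome `logit(p) = logit(risk₀) + β_causal·(x−μ) + Σ α_k g_k + δU`
with per-variant direct effects `α_k` (pleiotropy) and `δ = γ =`
`confounder_strength`. Case–control cohorts oversample cases from repeated
population draws (baseline risk 1% at the mean exposure) until the
configured case fraction is met; exposure is recorded only in population
(exposure-arm) cohorts. For site-stratified testing an alternative
competing-liabilities outcome gives each tumour site (proximal/distal/
rectum) its own logistic event with a site-specific causal effect.

Defaults that are design choices, not estimates from any dataset: allele
frequencies 0.21–0.79; exposure mean log(38) nmol/L and SD 0.5 on the log
scale (a deficient northern-latitude population); case covariates age/sex/
BMI independent of genotype, so the confounder scan is null by construction.
Scenario presets: `null` (β_causal = 0), `observational_effect`
(OR 0.83 per exposure SD, i.e. β_causal = ln 0.83/0.5 per unit
log-exposure), `pleiotropic` (α_k = 0.05 for all k, directional), and
`confounded` (γ = δ = 0.3).

The generator reproduces the *statistical* structure the estimators assume —
independent variants, additive genetic effects, logistic disease risk — and
deliberately omits LD, population stratification, age-dependent incidence,
genotyping error and selection effects. Passing simulation tests therefore
validates the estimators under their own assumptions; they say nothing about
robustness to violations the real cohorts might harbour.

## What the test suite establishes, and at what scale

Deterministic checks reproduce the full summary-MR panel from the bundled
six-variant instrument and the analytic power values for the published
study designs. Stochastic checks (fixed seeds throughout): IVW type-I error
within the 95% binomial band of 0.05 under the null generative model (two
cohorts of 5,000; 1,000 seeds); recovery of the generating causal effect by
both estimator routes (50,000 per sample, 200 replicates, agreement within
3 Monte-Carlo SEs); ≥ 80% detection of the planted directional pleiotropy
by the Egger intercept at the preset α_k; DerSimonian–Laird τ² recovery
(2,000 meta-level replicates); and ~95% pooled-CI coverage in a five-cohort
null emulation using the real studies' case/control counts (100
replicates). Smaller-scale variants of several of these run in the module
test files; sizes were chosen so the full suite completes in minutes on a
single CPU while keeping Monte-Carlo error well below the tested margins.

## Limitations

Individual-level results from the restricted cohorts (e.g. the published
pooled OR 1.03 or F = 46.0) are not reproducible without data access and
are intentionally not asserted anywhere; the individual-level arm is
validated by its invariances and calibration on synthetic cohorts instead.
The exposure-beta scale of the external GWAS (raw vs. standardized log
25-OHD) is ambiguous in the source tables; estimates are reported per unit
log-transformed 25-OHD without attempting an SD conversion. No LD-aware or
multivariable-MR modelling, no mode-based estimators, no non-linear MR, no
genotype QC/imputation.
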