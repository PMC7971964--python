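# Methods

This note documents the statistical conventions, the synthetic
generative model, the numerical choices, and the replicate sizes the
package uses, in enough detail to re-derive every computed quantity.

## Design overview

Two estimates of the effect of a sleep exposure on each of 113
metabolomic traits are produced and compared:

1. **Observational arm (AMV).** Per cohort, OLS of the log-transformed,
   within-cohort-standardized metabolite on the exposure plus age, sex
   and BMI; the exposure coefficient (SD log-metabolite per exposure
   unit) is pooled across cohorts by inverse-variance meta-analysis
   (fixed-effect headline, DerSimonian–Laird random-effects alongside).
   Binary exposures are coded 1 = index category (usually-insomnia,
   evening preference, short/long duration), 0 = reference; duration is
   in hours. An unadjusted variant (exposure only) is available for
   contrast. Missingness is handled by listwise deletion; no interaction
   terms; sex coded 0/1.
2. **Genetic arm (two-sample MR).** Instruments per exposure: SNPs at
   p < 5·10⁻⁸ (strict inequality), palindromic pairs removed, greedy LD
   clumping at r² > 0.001 keeping the smallest p-value (ties broken by
   lexicographic snp_id for determinism), optional reorientation to the
   risk-increasing allele for chronotype-style codings. MR runs against
   each of four independent metabolite GWAS datasets and the per-dataset
   IVW estimates are pooled by fixed-effect meta-analysis; Q statistics
   are reported per dataset, not pooled.
3. **Triangulation.** Both arms are thresholded at α/m with α = 0.05 and
   m = 17 effective tests (the number of principal components explaining
   ~95% of the panel's variance; `effective_tests_from_panel` recomputes
   m for any panel). A metabolite selected by either arm is `consistent`
   if the other arm has the same non-zero sign and p < 0.05, otherwise
   `not_consistent`; unselected metabolites are `not_selected`. When
   both arms pass the threshold the rule is symmetric, and opposite
   signs are classed `not_consistent`. Panel-wide agreement is the OLS
   line of MR on AMV estimates (MR on the vertical axis) with its R².
   Selection and consistency always use the IVW (meta-analysed)
   p-values; Egger and weighted median are reported as sensitivity
   analyses but never gate verdicts.

## Estimator conventions

* **Wald ratio** (1 SNP): θ̂ = β̂_Y/β̂_X, first-order SE σ_Y/|β̂_X|.
* **IVW, multiplicative random effects** (≥2 SNPs): WLS through the
  origin with weights 1/σ_Yj²; SE = (Σwβ̂_X²)^(−1/2) · max(1, √(Q/(J−1))).
  The inflation factor never deflates. Normal two-sided p-values.
  Weights are first-order (σ_X ignored), the standard two-sample MR
  choice.
* **MR-Egger** (≥3 SNPs): rows reoriented so every β̂_X ≥ 0, then WLS
  with free intercept, weights 1/σ_Yj²; slope and intercept SEs scaled
  by max(1, √(Q/(J−2))); p-values from t(J−2). An error is raised when
  all β̂_X are identical (slope unidentifiable).
* **Weighted median** (≥2 SNPs): per-SNP ratios sorted; standardized
  cumulative-weight midpoints p_j = (S_j − w_j/2)/S_J with
  w_j = β̂_Xj²/σ_Yj²; estimate by linear interpolation at p = 0.5 (clamped
  to the extreme ratio when 0.5 falls outside the midpoint range). SE =
  SD of the estimate over 1,000 parametric-bootstrap draws
  (β̂_X, β̂_Y resampled at their reported SEs; explicit seed); normal CI/p.
* **Meta-analysis**: fixed-effect weights 1/se²; DerSimonian–Laird
  τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)), re-weighted with 1/(se²+τ²).
  REML is not implemented. k = 1 is allowed for the fixed model (Q
  p-value undefined → NaN).
* **Instrument strength**: per-SNP F = (β̂/σ)²; the *total F* is the sum
  over instruments, the convention consistent with published magnitudes
  (a few hundred to ~14,000 for sleep-trait GWAS).
* 95% CIs: θ̂ ± 1.959964·SE (normal) or the t(J−2) quantile for Egger.

**Harmonization.** Outcome records are aligned per SNP to the exposure's
effect allele: identical pair — unchanged; swapped — β negated, EAF
complemented; strand complement (or complement-swap) — complemented
first, then as above; anything else dropped (`allele_mismatch`). Because
palindromic SNPs are excluded upstream, strand resolution is
unambiguous and no frequency-based inference is needed; EAF may even be
absent. Matching is by snp_id (a strict mode additionally checks
chrom/pos). Flip-invariance — recoding every outcome record on its other
allele changes nothing downstream — is enforced by test.

## The synthetic generative model

The generator emulates the study the pipeline targets; its defaults are
the package's study conditions.

* **Genome.** 80 candidate SNPs in LD blocks of 2 (within-block
  r² = 0.7, zero between), MAF ~ U(0.05, 0.5) shared within a block,
  allele pairs uniform over ordered pairs (so ~1/3 are palindromic and
  exercise that exclusion; `exclude_palindromic_alleles` disables this
  for estimator benchmarks). Dosages come from a block-common Bernoulli
  copula: each haplotype allele copies a block-level uniform with
  probability λ = r²^(1/4), which makes the dosage r² equal the target.
  The emitted LD matrix is the target block matrix.
* **Exposure.** Standard-normal liability = genetic score (variance
  `instrument_h2`) + 0.25·U + (0.1, 0.05, 0.15)·(age_z, sex, BMI_z) +
  residual. Binary exposures threshold at prevalence 0.28 (an
  insomnia-like "usually vs. rest" coding); continuous exposures map to
  hours as 7.2 + 1.1·liability. With h2 = 0.2 at the desk-scale exposure
  GWAS n = 20,000, selected instruments carry a total F in the low
  thousands — the same weak-instrument regime as the published
  sleep-trait GWAS (total F from ~200 to ~14,000), which is what
  matters for estimator behaviour; the million-scale biobank n itself is
  not emulated.
* **Metabolites.** Log-scale value = θ_t·X + pleiotropic SNP effects +
  u_t·U + (0.05, 0.1, 0.2)·covariates + correlated noise. Noise loads on
  17 latent factors scaled to carry 95% of the noise variance (unit-norm
  random loadings rows), residuals independent — reproducing a panel in
  which ~17 components explain ~95% of total variance. Residual variance
  is set so each metabolite has population variance 1 before the within-
  sample standardization (a config error is raised if the explained
  variance budget exceeds 1). Cohort tables emit exp(log-value) so the
  regression arm exercises its own log-transform. Gaussian noise on the
  log scale is assumed throughout.
* **Default effects.** Six named signals (±0.04–0.08 SD) plus a diffuse
  N(0, 0.025) background across the panel, and per-metabolite confounder
  loadings u_t ~ N(0, 0.05)·U. These scales were fixed once so that, at
  the default sample sizes, the pipeline reproduces the regime the field
  reports for sleep–metabolome studies: roughly a dozen of 113
  metabolites passing 0.0029 in the observational arm, a handful in MR,
  a few consistent verdicts, and panel-wide concordance R² of order
  0.2–0.4. They are conditions, not tuning knobs.
* **Estimand bookkeeping.** Because metabolites are standardized, the
  SD-scale estimand is θ_t divided by the metabolite's population SD,
  which departs from 1 through exposure–confounder/covariate cross
  covariances. The truth record carries this `theta_sd` exactly (the
  liability→observed attenuation φ(c) enters the cross-covariances;
  treating the sex indicator as approximately normal there contributes
  error of order its cubed loading, ~10⁻⁴). All recovery statements
  score against `theta_sd`.
* **Sampling paths.** Summary statistics are produced by actually
  regressing simulated phenotypes on dosages SNP-by-SNP in two
  independently drawn samples (no overlap, as in a clean two-sample
  design; exposure GWAS on the observed 0/1 or hours scale, metabolites
  standardized after log), so SEs, Q behaviour and weak-instrument
  attenuation emerge naturally. The `analytic` path instead draws
  β̂ ~ N(β, se) from the asymptotic law — appropriate for large-n
  calibration checks. AMV cohorts replace the genetic liability variance
  with extra residual noise (prevalence preserved); participants with
  exclusion conditions are assumed removed upstream, so tables are clean
  and complete.
* **Randomness.** One seed feeds named sub-streams (truth, exposure
  sample, per-dataset outcome samples, per-cohort, analytic), so adding
  a component never perturbs another's draws; identical config + seed is
  bit-reproducible, and all result TSVs are written/read at 17
  significant digits so resumed or re-read runs are bit-identical.

## Replicate studies and their sizes

The `experiments` module runs the characterization studies; sizes were
chosen so each completes in minutes on one CPU while Monte-Carlo error
stays well inside the claims being checked.

* **Recovery** (200 replicates): θ = 0.5, 50 independent, equally strong,
  non-palindromic instruments; exposure GWAS n = 50,000 with h2 = 0.25
  (per-SNP F ≈ 140, total ≈ 7,000 — matching the published order); four
  outcome datasets with the published sizes 24,925 / 6,616 / 4,734 /
  2,343; full selection → harmonization → per-dataset IVW → fixed-effect
  meta. Expected attenuation from instrument-estimation noise is
  θ·J/ΣF ≈ 0.004, inside the |bias| < 0.01 claim; coverage is checked
  within 3 Monte-Carlo SEs of 0.95.
* **Type-I error** (500 replicates): same design with θ = 0, one outcome
  dataset, analytic path; the max(1,·) SE inflation makes the test
  mildly conservative (observed rates ~0.03–0.04).
* **Pleiotropy** (200 replicates): 10 positively oriented instruments,
  4 carrying directional pleiotropy α ~ N(0.1, 0.05); valid SNPs hold
  >50% of the weight on average. Checks: mean Egger intercept positive,
  IVW biased away from truth, weighted-median mean estimate closer to
  truth than IVW. Estimator-only study: all 10 SNPs are harmonized
  without the selection filter, which is not under test here.

Passing these says the *machinery* is correct and calibrated under the
generative model; it does not certify real-data findings, where LD is
not block-exchangeable, effects are not Gaussian, instruments can act
through unmodelled pathways, and confounding is richer than one latent
U plus three covariates.

## Known limitations

* No Steiger filtering, MR-PRESSO, mode-based or multivariable MR; no
  proxy-SNP lookup; no genome-build handling — ids are authoritative.
* LD is block-exchangeable; clumping is all-pairs with no physical
  window (a window would only matter with realistic LD maps).
* The weighted-median SE is bootstrap-based; with very few SNPs its
  normal CI is approximate.
* The liability→observed-scale mapping for binary exposures is the
  standard φ(c) linearization in the truth bookkeeping only; the data
  themselves are generated nonlinearly through the threshold.
* Fixed-effect pooling assumes the four outcome GWAS estimate the same
  quantity; dataset heterogeneity surfaces only through per-dataset Q.
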