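# Methods

## The model

Two-sample summary-data Mendelian randomization treats genetic variants as
instrumental variables for a modifiable exposure. For SNP *j* the exposure
GWAS supplies the per-allele association β̂ₓⱼ with standard error σₓⱼ, and an
independent outcome GWAS supplies β̂ᵧⱼ, σᵧⱼ for the same allele. Under the
instrumental-variable assumptions (the SNP is associated with the exposure,
shares no confounder with the outcome, and affects the outcome only through
the exposure), each Wald ratio θⱼ = βᵧⱼ/βₓⱼ identifies the same causal slope
b, and the estimators differ in how they pool the ratios and which
assumption violations they tolerate.

The motivating application is serum calcium (instrumented by 13
genome-wide-significant SNPs from a 20,611-person GWAS meta-analysis, effects
in mg/dl per allele, dominated by the calcium-sensing-receptor locus) against
coronary artery disease and cardiometabolic risk factors; binary outcomes are
analysed on the log-odds scale and exponentiated into odds ratios per 1 mg/dl
of calcium.

## Estimators

**IVW, fixed effects.** β̂ = Σβ̂ₓⱼβ̂ᵧⱼσᵧⱼ⁻² / Σβ̂ₓⱼ²σᵧⱼ⁻², SE =
(Σβ̂ₓⱼ²σᵧⱼ⁻²)^(−1/2). No overdispersion scaling is applied anywhere in the
package: the σᵧ are treated as known, so all intervals are fixed-effect
normal-theory intervals (estimate ± z₁₋α/₂·SE, α = 0.05 by default).

**Correlated GLS.** When instruments are in LD the ratio estimates are not
independent; with Ωⱼₖ = σᵧⱼσᵧₖρⱼₖ (ρ the *signed* LD correlation — a signed
matrix is required for Ω to be a valid covariance; squared correlations
would not be), β̂ = (β̂ₓᵀΩ⁻¹β̂ₓ)⁻¹β̂ₓᵀΩ⁻¹β̂ᵧ. Ω must be positive definite;
the fit reports the offending eigenvalue otherwise, and pairs with |ρ| = 1
are rejected with advice to prune first. With identity ρ this reduces to IVW
exactly (a regression-tested identity).

**Weighted median.** Ratios are ordered with normalized first-order
inverse-variance weights wⱼ; the cumulative midpoint of the j-th ratio is
pⱼ = Σₖ≤ⱼwₖ − wⱼ/2 and the estimate linearly interpolates θ against p at
p = 0.5, clamping to the extreme ratio when 0.5 falls outside [p₁, p_K]. The
SE is the standard deviation over n_boot (default 10,000) parametric
bootstrap replicates drawing β̂ₓⱼ*, β̂ᵧⱼ* independently from normal(β̂, σ̂);
the point estimate is seed-independent, only the SE consumes the seed. The
construction is defined for (approximately) uncorrelated instruments, so the
pipeline applies it to the independent subset only; any residual LD is
deliberately ignored.

**MR-Egger.** Each pair is oriented so β̂ₓⱼ > 0, then β̂ᵧ is regressed on
β̂ₓ with a free intercept and weights σᵧ⁻². The intercept estimates average
directional pleiotropy (two-sided normal test); the slope is the
pleiotropy-adjusted estimate. The covariance is the unscaled (XᵀWX)⁻¹,
consistent with the fixed-effect convention above. Constraining the
intercept to zero recovers the IVW slope algebraically — kept as a
regression test. The NOME diagnostic is I²₍GX₎ = max(0, (Q₍GX₎ − (K−1))/Q₍GX₎)
with Q₍GX₎ the σₓ⁻²-weighted heterogeneity of the β̂ₓ about their weighted
mean; values near 1 mean the exposure effects are precise relative to their
spread and Egger attenuation is negligible.

**Wald SE.** The per-SNP ratio SE is first-order (σᵧ/|β̂ₓ|), the standard
summary-data convention; a second-order option adding the β̂ₓ-variance term
is available behind a flag.

## Instrument selection

Filters run in sequence — genome-wide significance (p strictly below 5×10⁻⁸),
LD pruning, pleiotropy exclusion — and the accounting identity (inputs =
failed + pruned + excluded + retained) is enforced structurally. Pruning is
greedy in ascending p (ties broken by rsID for determinism): a SNP is kept
iff its squared correlation with every already-kept SNP is below the
threshold (default r² ≥ 0.8 discards). This greedy rule equals the
p-priority-lexicographically-first maximal feasible subset, and the test
suite checks it against an exhaustive-enumeration oracle up to K = 8. The
same greedy rule with a stricter threshold extracts the near-independent
subset used for the main analysis; the default independence threshold is
r² < 0.05, which reproduces the packaged four-SNP calcium instrument —
r² < 0.01 is the stricter convention some analyses use, and both are plain
config values.

Instrument strength is F = R²(n−1−K)/((1−R²)K). The aggregate R² is a user
input: published GWAS report it directly, and how per-SNP R² values combine
under LD is not derivable from summary data alone. For synthetic data, where
the exposure variance is known, the helper `snp_r2` gives per-SNP
R² = 2·MAF·(1−MAF)·β²/var(X). At R² = 0.01, K = 4, n = 20,611 the formula
gives F = 52.0, the strength of the packaged calcium instrument.

## Harmonization

Outcome records are aligned to exposure effect alleles: identical pairs pass,
swapped pairs flip the outcome beta and complement its EAF, and otherwise one
strand flip (A↔T, C↔G) is attempted before declaring a mismatch — consortium
files mix strand conventions, so refusing to flip would discard usable SNPs.
Palindromic SNPs (A/T, C/G) cannot be strand-resolved from alleles; the
default policy drops them when the outcome EAF is missing or in [0.42, 0.58]
and otherwise resolves strand by EAF concordance across 0.5; `strict` (drop
all) and `keep` (trust labels) policies are available. Missing EAF on
non-palindromic SNPs is tolerated — the estimators never use it.
Harmonization is idempotent and every dropped SNP carries a machine-readable
reason code into the run log.

## Power and overlap

Post-hoc power assumes unit-variance exposure and outcome: the IV z-statistic
is approximately normal with non-centrality |b|√(n·r²), so
power = 1 − Φ(z₁₋α/₂ − ncp) + Φ(−z₁₋α/₂ − ncp), exactly α at b = 0. Inputs
are therefore in SD units. A Monte-Carlo oracle (simulating the estimator's
sampling distribution at the same (b, n, r²)) confirms the closed form within
two Monte-Carlo SEs at 10⁴ replicates. Example at study scale: a 0.03-SD
effect with n = 46,186 and r² = 0.01 has power ≈ 0.10 — a two-sided test this
size is very likely to miss such an effect. Sample overlap is the arithmetic
100·overlap·n_exposure/n_outcome; reported percentages round to the nearest
integer (e.g. 50% assumed overlap of 20,611 in 86,995 → 11.85 → 12%).

## Synthetic data

The generator emulates what the analysis assumes about reality: dosages 0/1/2
under Hardy-Weinberg, additive SNP effects on a continuous exposure
(X = Σaⱼgⱼ + ε), a linear or logistic outcome (Y = bX + Σpleioⱼgⱼ + ε′, or
the logistic analogue with an intercept setting base prevalence ≈ 25%), LD
via a Gaussian copula at the haplotype level, and two disjoint cohorts per
study. The copula's latent correlation is calibrated per SNP pair by
inverting the bivariate-normal orthant probability, so the realized *dosage*
correlation matches the target (empirically within ~0.01 for common
variants); targets outside the Fréchet bounds for a MAF pair raise a
generation error naming the pair. Everything is bit-reproducible from the
config seed.

Defaults mirror the motivating study: the four main-analysis calcium SNPs'
effects (0.022, 0.021, 0.061, 0.027 mg/dl) and MAFs, an exposure cohort of
20,611, and exposure noise SD 0.5 (a plausible serum-calcium spread; a
convenience default, not an estimated quantity). Binary-outcome betas are
per-SNP logistic log-odds; their known non-collapsibility bias at large
effects means binary recovery checks should use small b.

What the generator does *not* emulate — realistic human LD panels,
imputation noise, case-control ascertainment, population stratification,
winner's curse in instrument discovery — bounds what passing tests show:
they validate the estimators under the model's own assumptions, not
robustness to every failure mode of real consortium data.

## Simulation-study design choices

The Monte-Carlo recovery and robustness studies in the acceptance suite use
500 replicates with 20,000 individuals per cohort, four instruments, and
per-allele exposure effects three times the packaged calcium values
(aggregate R² ≈ 4%, first-stage F ≈ 200). The inflation is deliberate: those
studies test the correctness of the combination rules under the
no-measurement-error regime they assume, and at the study's own instrument
strength (F ≈ 52, or ≈ 21 with the default noise SD at n = 20,000) the known
finite-sample weak-instrument attenuation of order b/F would be comparable to
the Monte-Carlo resolution of a 500-replicate mean — the test would measure
weak-instrument bias, a real and documented phenomenon, rather than
implementation error. The weighted-median bootstrap uses 400 replicates
inside these studies (SE resolution is what coverage needs, not the 10,000
default aimed at one-shot analyses). The pleiotropy study plants a direct
effect of 0.05 on the first (weakest) instrument, about 9% of the IVW
weight, giving IVW a bias near +0.08 that the weighted median cuts roughly
four-fold and that the Egger intercept detects well above the nominal 5%
rate.

The one-sample 2SLS comparison uses n = 50,000 so the asymptotic equality of
IVW-on-summaries with individual-level 2SLS holds within 0.02 on a single
replicate.

## Numerical and degenerate-input conventions

* LD matrices are validated symmetric within 1e−8, then exactly symmetrized;
  entries clipped to [−1, 1]; positive definiteness is required only where Ω
  is inverted.
* Significance filtering is strict (< threshold); records with missing p
  never pass.
* p-value ties in pruning break by rsID; greedy output is input-order
  invariant.
* Ratio/median estimators refuse β̂ₓ = 0 (undefined ratio) and K < 3
  (median, Egger); IVW refuses all-zero β̂ₓ.
* I²₍GX₎ truncates at 0 (Q < K−1 happens by chance); the weighted-median
  interpolation clamps at the boundary ratios.
* Bootstrap draws hitting β̂ₓ* = 0 exactly are nudged to the smallest
  positive float (measure-zero event, keeps the vectorized path total).
* Exact association fits (SE 0 from `linregress`) are floored at the
  smallest positive float so records stay valid.

## Known limitations

* Random-effects IVW, mode-based estimators, multivariable MR and outlier
  removal (MR-PRESSO-style) are out of scope.
* MR-Egger is fit on the independent subset only; a correlated-Egger variant
  is not provided.
* The first-order Wald SE ignores σₓ and any exposure/outcome covariance;
  with weak instruments intervals are accordingly optimistic.
* Power is for standardized continuous outcomes only; binary-outcome power
  is not implemented.
* The packaged LD matrix and candidate panel are synthetic reconstructions
  (the original supplementary matrix is not redistributed); they preserve
  the qualitative structure, not the original pairwise values.
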