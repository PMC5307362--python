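# summr — two-sample summary-data Mendelian randomization

`summr` estimates the causal effect of an exposure on an outcome from GWAS
summary statistics, using genetic variants as instrumental variables. It was
built around a concrete epidemiological question — does higher serum calcium
raise the risk of coronary artery disease and its cardiometabolic risk
factors? — and ships the 13 genome-wide-significant serum-calcium SNPs
(per-allele effects in mg/dl from a 20,611-person GWAS meta-analysis) as a
packaged instrument set, but every component is generic: any exposure/outcome
pair with tabular summary statistics and an LD matrix will do.

It is aimed at genetic epidemiologists and biostatisticians who want a
scriptable, fully testable Python implementation of the standard summary-data
MR toolbox, including an LD-aware estimator for correlated instruments and a
synthetic-data generator so the whole pipeline can be exercised and validated
with no external downloads.

## What it computes

For SNP *j*, let β̂ₓⱼ (SE σₓⱼ) be its effect on the exposure and β̂ᵧⱼ (SE
σᵧⱼ) its allele-aligned effect on the outcome. The per-SNP Wald ratio is
θ̂ⱼ = β̂ᵧⱼ / β̂ₓⱼ with first-order SE σᵧⱼ/|β̂ₓⱼ|. The combination
estimators are:

* **IVW (fixed effects)** — β̂ = Σⱼ β̂ₓⱼβ̂ᵧⱼσᵧⱼ⁻² / Σⱼ β̂ₓⱼ²σᵧⱼ⁻², with
  SE (Σⱼ β̂ₓⱼ²σᵧⱼ⁻²)^(−1/2); equivalent to weighted regression of β̂ᵧ on
  β̂ₓ through the origin, and asymptotically equal to two-stage least
  squares on individual-level data when instruments are uncorrelated.
* **Correlated GLS** — the same regression with weight matrix Ω⁻¹,
  Ωⱼₖ = σᵧⱼσᵧₖρⱼₖ where ρ is the signed LD correlation matrix; lets
  correlated SNPs contribute without being double-counted.
* **Weighted median** — the 50% point of the inverse-variance-weighted
  Wald-ratio distribution; consistent when valid instruments carry ≥ 50% of
  the weight; SE by parametric bootstrap.
* **MR-Egger** — weighted regression of β̂ᵧ on β̂ₓ *with* an intercept;
  the intercept estimates average directional pleiotropy and its two-sided
  test probes the exclusion restriction; the slope is a pleiotropy-adjusted
  estimate. The I²₍GX₎ statistic reports how severely measurement error in
  β̂ₓ (NOME violation) attenuates the slope.

Supporting machinery: instrument selection (genome-wide significance filter,
greedy LD pruning at r² ≥ 0.8 keeping the smaller-p SNP, pleiotropy exclusion
list, greedy independent-subset extraction), allele harmonization with strand
flipping and palindromic-SNP policies, the first-stage F-statistic
F = R²(n−1−K)/((1−R²)K), post-hoc power for standardized continuous outcomes,
and the two-sample overlap percentage.

## Worked example

Simulate a two-sample study with a true causal effect of 0.5 outcome units
per exposure unit (four valid instruments, 20,000 individuals per cohort),
then estimate it from the summary statistics alone:

```python
import summr
from summr.simulate import SimConfig, two_sample_summaries

cfg = SimConfig(seed=42, b=0.5, a=(0.066, 0.063, 0.183, 0.081),
                n_exposure_cohort=20000, n_outcome_cohort=20000)
exposure, outcome, ld = two_sample_summaries(cfg)
hs = summr.harmonize(exposure, outcome, ld)

for label, res in [("IVW", summr.ivw(hs)),
                   ("GLS", summr.gls_correlated(hs)),
                   ("Weighted median", summr.weighted_median(hs, n_boot=10000, seed=42))]:
    print(f"{label:16s} beta={res.beta:.3f}  se={res.se:.3f}  "
          f"95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]")
res, diag = summr.egger(hs)
print(f"{'MR-Egger':16s} beta={res.beta:.3f}  se={res.se:.3f}  "
      f"intercept={res.intercept:.4f} (p={res.intercept_p:.2f})  I2_GX={diag.i2_gx:.3f}")
print(f"F-statistic      {summr.f_statistic(0.01, 4, 20611).F:.1f}")
```

Output:

```
IVW              beta=0.535  se=0.072  95% CI [0.394, 0.675]
GLS              beta=0.535  se=0.072  95% CI [0.394, 0.676]
Weighted median  beta=0.518  se=0.080  95% CI [0.362, 0.675]
MR-Egger         beta=0.485  se=0.164  intercept=0.0055 (p=0.74)  I2_GX=0.981
F-statistic      52.0
```

Every interval covers the true 0.5; the Egger intercept is consistent with
zero (no directional pleiotropy was simulated), and I²₍GX₎ ≈ 0.98 says the
SNP-exposure effects are precise enough for the Egger slope to be trusted.
The last line is the first-stage strength of the packaged four-SNP calcium
instrument at its published aggregate R² of 1%.

The estimators are also available as scikit-learn-style classes
(`IVWEstimator`, `CorrelatedGLSEstimator`, `WeightedMedianEstimator`,
`EggerRegression`) with `fit(X, y, ...)`, fitted `beta_`/`se_`/`ci_*_`
attributes and `get_params`/`clone` support.

A CLI covers the same ground end to end:

```bash
summr simulate --seed 3 --b 0.5 --outdir sim/
summr estimate --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
               --ld sim/ld.tsv --seed 4
summr select --summary candidates.tsv --ld ld.tsv --exclusion pleio.txt
summr power --b 0.03 --n 46186 --r2 0.01
summr overlap --n-exposure 20611 --n-outcome 86995 --proportion 0.5
summr run --config analysis.yaml     # full Table-style results file
```

## Layout

```
src/summr/
  records.py     SummaryRecord, LDMatrix, HarmonizedInstrumentSet
  io.py          delimited summary-stat / LD readers and writers
  harmonize.py   allele alignment, strand flips, palindromic policies
  selection.py   significance filter, LD pruning, pleiotropy exclusion, F
  estimators.py  IVW, correlated GLS, weighted median, MR-Egger (+ I2_GX)
  diagnostics.py post-hoc power, sample-overlap percentage
  simulate.py    synthetic cohorts, association scans, 2SLS oracle
  datasets.py    packaged calcium instruments and the 128-SNP panel
  pipeline.py    config-driven multi-outcome analysis
  cli.py         command-line interface
```

See `docs/methods.md` for the statistical model, assumptions, numerical
choices and known limitations.
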