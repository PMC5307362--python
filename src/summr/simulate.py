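"""Synthetic two-sample GWAS cohorts with known causal ground truth.

Emulates the data-generating process a summary-data MR analysis assumes:
additive multi-SNP genetics of a continuous exposure, a linear (or logistic)
outcome model with a configurable causal effect ``b`` and optional direct
SNP-to-outcome (pleiotropic) paths, LD between SNPs, and the two-sample
design in which exposure and outcome summary statistics come from disjoint
cohorts. Everything downstream of :func:`two_sample_summaries` is the same
machinery a real analysis would use, so every estimator is testable with no
external downloads.

Genotypes are biallelic dosages 0/1/2 drawn under Hardy-Weinberg; LD is
induced by a Gaussian copula at the haplotype level whose latent correlation
is calibrated per SNP pair so the *dosage* correlation matches the requested
``ld_r`` (good to within a few hundredths for common variants; rare-variant
targets near the Frechet bound are rejected as infeasible).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .exceptions import GenerationError
from .io import empirical_ld
from .records import LDMatrix, SummaryRecord

#: Table-style defaults: per-allele mg/dl effects and MAFs of the four
#: mutually independent serum-calcium SNPs used for the motivating analysis.
DEFAULT_MAF = (0.1248, 0.4355, 0.0942, 0.1040)
DEFAULT_A = (0.022, 0.021, 0.061, 0.027)

_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a simulated study.

    ``a`` are per-allele SNP-exposure effects (exposure units per allele),
    ``b`` the true causal effect of the exposure on the outcome, ``pleio``
    per-SNP direct SNP-outcome effects (zero for valid instruments).
    ``ld_r`` is a K x K target dosage-correlation matrix (None = independent
    SNPs). The binary outcome uses a logistic model with the same linear
    predictor and ``logit_intercept`` setting the base prevalence.
    """

    seed: int
    K: int = 4
    maf: Tuple[float, ...] = DEFAULT_MAF
    a: Tuple[float, ...] = DEFAULT_A
    b: float = 0.0
    pleio: Tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    ld_r: Optional[Tuple[Tuple[float, ...], ...]] = None
    outcome_type: str = "continuous"
    n_exposure_cohort: int = 20611
    n_outcome_cohort: int = 20000
    exposure_noise_sd: float = 0.5
    outcome_noise_sd: float = 1.0
    logit_intercept: float = -1.1
    snp_ids: Optional[Tuple[str, ...]] = None

    def __post_init__(self):
        if len(self.maf) != self.K or len(self.a) != self.K or len(self.pleio) != self.K:
            raise GenerationError("maf, a and pleio must all have length K")
        if self.snp_ids is not None and len(self.snp_ids) != self.K:
            raise GenerationError("snp_ids must have length K")
        if any(not (0.0 < m <= 0.5) for m in self.maf):
            raise GenerationError("maf entries must lie in (0, 0.5]")
        if self.outcome_type not in ("continuous", "binary"):
            raise GenerationError(f"unknown outcome_type {self.outcome_type!r}")
        if self.ld_r is not None:
            m = np.asarray(self.ld_r, dtype=float)
            if m.shape != (self.K, self.K):
                raise GenerationError(f"ld_r must be K x K, got {m.shape}")

    @property
    def ids(self) -> List[str]:
        if self.snp_ids is not None:
            return list(self.snp_ids)
        return [f"snp_{j + 1}" for j in range(self.K)]

    def alleles(self, j: int) -> Tuple[str, str]:
        return _ALLELE_CYCLE[j % len(_ALLELE_CYCLE)]


@dataclass
class SyntheticCohort:
    """Individual-level simulated data plus the config that generated it."""

    genotypes: np.ndarray  # (n, K) dosages 0/1/2
    exposure: np.ndarray   # (n,)
    outcome: np.ndarray    # (n,) continuous values or 0/1
    truth: SimConfig

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        if not np.isin(g, (0, 1, 2)).all():
            raise GenerationError("dosages must be 0, 1 or 2")
        n = g.shape[0]
        if self.exposure.shape != (n,) or self.outcome.shape != (n,):
            raise GenerationError("phenotype vectors must match genotype rows")


def _pair_latent_rho(target: float, p1: float, p2: float) -> float:
    """Latent Gaussian correlation giving haplotype-allele correlation ``target``.

    For Bernoulli(p) indicators thresholded from a bivariate normal with
    correlation rho, corr = (Phi2(t1, t2; rho) - p1 p2) / sqrt(p1 q1 p2 q2).
    Inverts that relation by bisection; raises if the target lies outside the
    achievable (Frechet) range for this MAF pair.
    """
    if target == 0.0:
        return 0.0
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def binary_corr(rho: float) -> float:
        cov = stats.multivariate_normal.cdf(
            [t1, t2], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        ) - p1 * p2
        return cov / denom

    lo, hi = -0.9999, 0.9999
    f_lo, f_hi = binary_corr(lo), binary_corr(hi)
    if not (f_lo <= target <= f_hi):
        raise GenerationError(
            f"LD target r = {target} infeasible for MAF pair ({p1}, {p2}): "
            f"achievable range [{f_lo:.3f}, {f_hi:.3f}]"
        )
    return float(optimize.brentq(lambda r: binary_corr(r) - target, lo, hi, xtol=1e-6))


def _latent_corr(ld_r: np.ndarray, maf: np.ndarray) -> np.ndarray:
    K = len(maf)
    latent = np.eye(K)
    for i in range(K):
        for j in range(i + 1, K):
            try:
                latent[i, j] = latent[j, i] = _pair_latent_rho(
                    float(ld_r[i, j]), float(maf[i]), float(maf[j])
                )
            except GenerationError:
                raise
            except Exception as exc:  # pragma: no cover - scipy edge cases
                raise GenerationError(
                    f"LD calibration failed for pair ({i}, {j}): {exc}"
                ) from exc
    # eigen-clip to the nearest PSD correlation matrix (pairwise calibration
    # can leave tiny negative eigenvalues)
    vals, vecs = np.linalg.eigh(latent)
    if vals[0] < 1e-8:
        vals = np.clip(vals, 1e-8, None)
        latent = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)
    return latent


def _draw_genotypes(rng: np.random.Generator, n: int, maf: np.ndarray,
                    latent_chol: Optional[np.ndarray]) -> np.ndarray:
    """Dosages as the sum of two independent haplotypes (Hardy-Weinberg)."""
    K = len(maf)
    if latent_chol is None:
        return rng.binomial(2, maf, size=(n, K)).astype(np.int8)
    thresh = stats.norm.ppf(maf)
    g = np.zeros((n, K), dtype=np.int8)
    for _ in range(2):
        z = rng.standard_normal((n, K)) @ latent_chol.T
        g += (z < thresh).astype(np.int8)
    return g


def simulate_cohort(config: SimConfig, n: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None) -> SyntheticCohort:
    """Draw one cohort (genotypes, exposure, outcome) from the config.

    Deterministic given the config's seed. ``n`` defaults to
    ``config.n_exposure_cohort``; pass an explicit ``rng`` to chain multiple
    cohorts off one seed sequence (as :func:`two_sample_summaries` does).
    """
    n = int(n if n is not None else config.n_exposure_cohort)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    maf = np.asarray(config.maf, dtype=float)
    a = np.asarray(config.a, dtype=float)
    pleio = np.asarray(config.pleio, dtype=float)

    chol = None
    if config.ld_r is not None:
        ld_r = np.asarray(config.ld_r, dtype=float)
        if not np.allclose(ld_r, np.eye(config.K)):
            chol = np.linalg.cholesky(_latent_corr(ld_r, maf))
    g = _draw_genotypes(rng, n, maf, chol)

    x = g @ a + rng.normal(0.0, config.exposure_noise_sd, size=n)
    eta = config.b * x + g @ pleio
    if config.outcome_type == "continuous":
        y = eta + rng.normal(0.0, config.outcome_noise_sd, size=n)
    else:
        prob = 1.0 / (1.0 + np.exp(-(config.logit_intercept + eta)))
        y = rng.binomial(1, prob).astype(float)
    return SyntheticCohort(genotypes=g, exposure=x, outcome=y, truth=config)


def association_scan(cohort: SyntheticCohort, trait: str = "exposure") -> List[SummaryRecord]:
    """Per-SNP GWAS-style summary statistics for the cohort.

    Continuous traits use simple linear regression of the trait on dosage;
    binary traits use per-SNP logistic regression (log-odds betas).
    Monomorphic SNPs have no defined SE and are dropped with a logged reason.
    """
    if trait not in ("exposure", "outcome"):
        raise ValueError(f"trait must be 'exposure' or 'outcome', got {trait!r}")
    y = cohort.exposure if trait == "exposure" else cohort.outcome
    binary = trait == "outcome" and cohort.truth.outcome_type == "binary"
    cfg = cohort.truth
    g = cohort.genotypes.astype(float)
    n = g.shape[0]
    records: List[SummaryRecord] = []
    for j, snp_id in enumerate(cfg.ids):
        dose = g[:, j]
        if dose.min() == dose.max():
            continue  # monomorphic: slope SE undefined
        ea, oa = cfg.alleles(j)
        eaf = float(dose.mean() / 2.0)
        if binary:
            model = sm.Logit(y, sm.add_constant(dose)).fit(disp=0)
            beta, se, p = model.params[1], model.bse[1], model.pvalues[1]
        else:
            res = stats.linregress(dose, y)
            beta, se, p = res.slope, res.stderr, res.pvalue
        se = max(float(se), np.finfo(float).tiny)  # exact fits report se = 0
        records.append(
            SummaryRecord(
                snp_id=snp_id, effect_allele=ea, other_allele=oa,
                beta=float(beta), se=float(se), eaf=eaf,
                pval=float(min(max(p, np.finfo(float).tiny), 1.0)), n=n,
            )
        )
    return records


def two_sample_summaries(
    config: SimConfig,
) -> Tuple[List[SummaryRecord], List[SummaryRecord], LDMatrix]:
    """Summary statistics from two disjoint cohorts sharing one genetic model.

    Cohort 1 (size ``n_exposure_cohort``) yields the exposure scan and the
    empirical LD matrix; cohort 2 (size ``n_outcome_cohort``) yields the
    outcome scan. Bit-reproducible given the config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_exp, rng_out = (np.random.default_rng(s) for s in ss.spawn(2))
    cohort_exp = simulate_cohort(config, n=config.n_exposure_cohort, rng=rng_exp)
    cohort_out = simulate_cohort(config, n=config.n_outcome_cohort, rng=rng_out)
    exp_records = association_scan(cohort_exp, "exposure")
    out_records = association_scan(cohort_out, "outcome")
    ld = empirical_ld(config.ids, cohort_exp.genotypes)
    return exp_records, out_records, ld


def twosls_oracle(cohort: SyntheticCohort) -> float:
    """Two-stage least squares slope from individual-level data.

    Stage 1 regresses the exposure on all dosages (with intercept); stage 2
    regresses the outcome on the fitted exposure. The asymptotic target of
    IVW with uncorrelated instruments, used as an independent oracle.
    """
    g = cohort.genotypes.astype(float)
    n = g.shape[0]
    design1 = np.column_stack([np.ones(n), g])
    if np.linalg.matrix_rank(design1) < design1.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient genotype matrix")
    coef1, *_ = np.linalg.lstsq(design1, cohort.exposure, rcond=None)
    xhat = design1 @ coef1
    design2 = np.column_stack([np.ones(n), xhat])
    coef2, *_ = np.linalg.lstsq(design2, cohort.outcome, rcond=None)
    return float(coef2[1])


def null_config(seed: int, **overrides) -> SimConfig:
    """A no-effect configuration (a = 0, b = 0, pleio = 0) for null checks."""
    base = SimConfig(seed=seed)
    zeros = tuple(0.0 for _ in range(base.K))
    return replace(base, a=zeros, b=0.0, pleio=zeros, **overrides)
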