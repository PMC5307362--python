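"""Instrument selection: significance filter, LD pruning, pleiotropy exclusion.

The selection pipeline mirrors standard practice for building a genetic
instrument from a published GWAS: keep genome-wide-significant hits
(p < 5e-8), discard the larger-p member of any pair in strong LD
(r-squared >= 0.8), drop SNPs with known pleiotropic associations, and
finally identify a mutually near-independent subset for estimators that
assume uncorrelated instruments. Instrument strength is summarized by the
first-stage F-statistic

    F = R^2 (n - 1 - K) / ((1 - R^2) K)

with R^2 the exposure variance explained by the instrument, K the number of
SNPs and n the first-stage sample size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, List, Optional, Sequence, Tuple

from .exceptions import ConfigError
from .records import LDMatrix, SummaryRecord

logger = logging.getLogger("summr.selection")


@dataclass(frozen=True)
class CandidateSNP(SummaryRecord):
    """A SummaryRecord annotated with a user-supplied pleiotropy flag."""

    pleiotropy_flag: bool = False

    @classmethod
    def from_record(cls, rec: SummaryRecord, pleiotropy_flag: bool = False) -> "CandidateSNP":
        kwargs = {f.name: getattr(rec, f.name) for f in fields(SummaryRecord)}
        return cls(pleiotropy_flag=pleiotropy_flag, **kwargs)


@dataclass
class SelectionReport:
    """Accounting of the selection pipeline.

    Invariant: n_input = n_failed_significance + n_pruned_high_ld +
    n_excluded_pleiotropy + len(retained_ids), and the independent subset is
    contained in the retained set.
    """

    n_input: int
    n_failed_significance: int
    n_pruned_high_ld: int
    n_excluded_pleiotropy: int
    retained_ids: List[str]
    independent_subset_ids: List[str]
    pruned_pairs: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        total = (self.n_failed_significance + self.n_pruned_high_ld
                 + self.n_excluded_pleiotropy + len(self.retained_ids))
        if total != self.n_input:
            raise ValueError(
                f"selection accounting broken: {self.n_input} input != "
                f"{self.n_failed_significance} + {self.n_pruned_high_ld} + "
                f"{self.n_excluded_pleiotropy} + {len(self.retained_ids)}"
            )
        if not set(self.independent_subset_ids) <= set(self.retained_ids):
            raise ValueError("independent subset not contained in retained set")

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_failed_significance": self.n_failed_significance,
            "n_pruned_high_ld": self.n_pruned_high_ld,
            "n_excluded_pleiotropy": self.n_excluded_pleiotropy,
            "n_retained": len(self.retained_ids),
            "retained_ids": list(self.retained_ids),
            "independent_subset_ids": list(self.independent_subset_ids),
        }


@dataclass(frozen=True)
class InstrumentStrength:
    """First-stage F-statistic inputs and value."""

    r2_total: float
    K: int
    n: int
    F: float


@dataclass
class SelectionConfig:
    """Thresholds for select_instruments.

    ``independence_r2`` defaults to 0.05: the r-squared bound under which a
    greedy subset of retained SNPs is treated as mutually independent for the
    estimators that require uncorrelated instruments (0.01 is the stricter
    alternative sometimes used; both are legitimate, see the methods note).
    """

    p_threshold: float = 5e-8
    r2_high: float = 0.8
    independence_r2: float = 0.05


def filter_significance(
    candidates: Sequence[CandidateSNP], p_threshold: float = 5e-8
) -> Tuple[List[CandidateSNP], List[CandidateSNP]]:
    """Partition candidates into (p strictly below threshold, the rest).

    Records with missing p-values never pass the filter.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ConfigError(f"p_threshold {p_threshold} outside (0, 1)")
    retained = [c for c in candidates if c.pval is not None and c.pval < p_threshold]
    rejected = [c for c in candidates if not (c.pval is not None and c.pval < p_threshold)]
    if not retained:
        logger.warning("significance filter retained zero of %d candidates", len(candidates))
    return retained, rejected


def _p_order(candidates: Iterable[CandidateSNP]) -> List[CandidateSNP]:
    # missing p sorts last; ties broken by rsID for determinism
    return sorted(candidates, key=lambda c: (c.pval if c.pval is not None else math.inf, c.snp_id))


def _greedy_independent(
    candidates: Sequence[CandidateSNP], ld: LDMatrix, r2_max: float
) -> Tuple[List[CandidateSNP], List[Tuple[CandidateSNP, CandidateSNP]]]:
    """Greedy max-retention subset: ascending p, keep a SNP iff its squared
    correlation with every already-kept SNP stays below ``r2_max``.

    Returns (kept, [(pruned, displacing kept SNP), ...]).
    """
    kept: List[CandidateSNP] = []
    displaced: List[Tuple[CandidateSNP, CandidateSNP]] = []
    for cand in _p_order(candidates):
        if cand.snp_id not in ld:
            raise ConfigError(f"SNP {cand.snp_id} absent from LD matrix")
        blocker = next(
            (k for k in kept if ld.pair_r(cand.snp_id, k.snp_id) ** 2 >= r2_max), None
        )
        if blocker is None:
            kept.append(cand)
        else:
            displaced.append((cand, blocker))
    return kept, displaced


def ld_prune(
    candidates: Sequence[CandidateSNP], ld: LDMatrix, r2_high: float = 0.8
) -> Tuple[List[CandidateSNP], List[CandidateSNP]]:
    """Discard the larger-p SNP of every pair with r-squared >= ``r2_high``.

    Greedy in ascending p (ties by rsID), so the result is invariant to the
    input order. Pruned SNPs are logged with the retained SNP that displaced
    them. Retained SNPs keep the original input order.
    """
    if not (0.0 < r2_high <= 1.0):
        raise ConfigError(f"r2_high {r2_high} outside (0, 1]")
    kept, displaced = _greedy_independent(candidates, ld, r2_high)
    for pruned, keeper in displaced:
        logger.info("ld_prune dropped %s (r2 >= %.3g with retained %s)",
                    pruned.snp_id, r2_high, keeper.snp_id)
    kept_ids = {c.snp_id for c in kept}
    retained = [c for c in candidates if c.snp_id in kept_ids]
    pruned = [c for c in candidates if c.snp_id not in kept_ids]
    return retained, pruned


def exclude_pleiotropic(
    candidates: Sequence[CandidateSNP],
) -> Tuple[List[CandidateSNP], List[CandidateSNP]]:
    """Split candidates on their pleiotropy flag (False -> retained)."""
    retained = [c for c in candidates if not c.pleiotropy_flag]
    excluded = [c for c in candidates if c.pleiotropy_flag]
    if candidates and not retained:
        logger.warning("all %d candidates flagged pleiotropic", len(candidates))
    return retained, excluded


def select_instruments(
    candidates: Sequence[CandidateSNP],
    ld: LDMatrix,
    config: Optional[SelectionConfig] = None,
) -> SelectionReport:
    """Run the full selection pipeline and return its accounting report.

    Order: significance filter, then LD pruning, then pleiotropy exclusion;
    finally a greedy independent subset (pairwise r-squared <
    ``config.independence_r2``) of the retained SNPs is identified for the
    estimators that assume uncorrelated instruments.
    """
    config = config or SelectionConfig()
    sig, failed = filter_significance(candidates, config.p_threshold)
    pruned_kept, pruned_out = ld_prune(sig, ld, config.r2_high)
    retained, pleio = exclude_pleiotropic(pruned_kept)
    indep, _ = _greedy_independent(retained, ld, config.independence_r2)
    indep_ids = [c.snp_id for c in retained if c.snp_id in {i.snp_id for i in indep}]
    report = SelectionReport(
        n_input=len(candidates),
        n_failed_significance=len(failed),
        n_pruned_high_ld=len(pruned_out),
        n_excluded_pleiotropy=len(pleio),
        retained_ids=[c.snp_id for c in retained],
        independent_subset_ids=indep_ids,
    )
    logger.info("selection report: %s", report.as_dict())
    return report


def f_statistic(r2_total: float, K: int, n: int) -> InstrumentStrength:
    """First-stage F-statistic F = R^2 (n - 1 - K) / ((1 - R^2) K).

    Requires 0 <= R^2 < 1, K >= 1 and n > K + 1.
    """
    if not (0.0 <= r2_total < 1.0):
        raise ConfigError(f"r2_total {r2_total} outside [0, 1)")
    if K < 1:
        raise ConfigError(f"K {K} must be >= 1")
    if n <= K + 1:
        raise ConfigError(f"n {n} must exceed K + 1 = {K + 1}")
    F = r2_total * (n - 1 - K) / ((1.0 - r2_total) * K)
    return InstrumentStrength(r2_total=r2_total, K=K, n=n, F=F)


def snp_r2(maf: float, beta: float, var_exposure: float) -> float:
    """Variance in the exposure explained by one SNP under Hardy-Weinberg:
    2 maf (1 - maf) beta^2 / var_exposure.

    Useful for synthetic data where the exposure variance is known; real
    analyses should take the aggregate R^2 from the source GWAS.
    """
    if not (0.0 < maf <= 0.5):
        raise ConfigError(f"maf {maf} outside (0, 0.5]")
    if var_exposure <= 0:
        raise ConfigError("var_exposure must be positive")
    return 2.0 * maf * (1.0 - maf) * beta ** 2 / var_exposure
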