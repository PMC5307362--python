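"""Core containers for GWAS summary statistics and harmonized instruments.

A two-sample Mendelian randomization analysis runs entirely on summary-level
inputs: per-SNP association records for the exposure and the outcome, plus a
matrix of pairwise LD correlations between the instrument SNPs. These types
validate their invariants at construction so downstream algebra can assume
clean inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import FormatError

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Watson-Crick complement of a single-base allele."""
    return _COMPLEMENT[allele]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G SNPs, whose strand cannot be resolved from alleles."""
    return _COMPLEMENT[effect_allele] == other_allele


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` — for the
    exposure in this package's motivating analysis that is mg/dl of serum
    calcium per allele; for outcomes it is log-odds (binary traits) or SD /
    raw trait units (continuous traits). ``eaf`` (effect-allele frequency) and
    ``n`` may be missing (None).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: Optional[float] = None
    pval: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES:
            raise FormatError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise FormatError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.snp_id}: effect and other allele are identical")
        if not math.isfinite(self.beta):
            raise FormatError(f"{self.snp_id}: non-finite beta")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise FormatError(f"{self.snp_id}: se must be positive and finite")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise FormatError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            raise FormatError(f"{self.snp_id}: pval {self.pval} outside (0, 1]")
        if self.n is not None and self.n <= 0:
            raise FormatError(f"{self.snp_id}: n must be positive")

    def flipped(self) -> "SummaryRecord":
        """The same association expressed for the other allele.

        Swaps the allele labels, negates beta and complements the frequency;
        |beta| and the SE are conserved.
        """
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def strand_flipped(self) -> "SummaryRecord":
        """The same association reported on the opposite strand."""
        return replace(
            self,
            effect_allele=complement(self.effect_allele),
            other_allele=complement(self.other_allele),
        )

    @property
    def is_palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


class LDMatrix:
    """Signed pairwise LD correlations over an ordered set of SNPs.

    Entries are correlations r (not r-squared): the generalized-least-squares
    estimator needs a valid covariance, which requires signed r. The matrix is
    validated to be square, symmetric (within ``tol``, then exactly
    symmetrized), unit-diagonal and bounded by 1 in absolute value.
    """

    def __init__(self, snp_ids: Sequence[str], r: np.ndarray, tol: float = 1e-8):
        snp_ids = list(snp_ids)
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise FormatError(f"LD matrix must be square, got shape {r.shape}")
        if r.shape[0] != len(snp_ids):
            raise FormatError(
                f"LD matrix dimension {r.shape[0]} != number of SNP ids {len(snp_ids)}"
            )
        if len(set(snp_ids)) != len(snp_ids):
            raise FormatError("duplicate SNP ids in LD matrix")
        if r.size == 0:
            self.snp_ids = snp_ids
            self.r = r
            self._index = {}
            return
        if not np.all(np.isfinite(r)):
            raise FormatError("LD matrix contains non-finite entries")
        if np.max(np.abs(r)) > 1.0 + tol:
            bad = float(np.max(np.abs(r)))
            raise FormatError(f"LD matrix entry with |r| = {bad} > 1")
        if np.max(np.abs(r - r.T)) > tol:
            raise FormatError(
                f"LD matrix asymmetric beyond tolerance {tol}: "
                f"max |r - r.T| = {np.max(np.abs(r - r.T)):.3g}"
            )
        if np.max(np.abs(np.diag(r) - 1.0)) > tol:
            raise FormatError("LD matrix diagonal departs from 1")
        r = 0.5 * (r + r.T)
        np.fill_diagonal(r, 1.0)
        np.clip(r, -1.0, 1.0, out=r)
        self.snp_ids = snp_ids
        self.r = r
        self._index = {s: i for i, s in enumerate(snp_ids)}

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def pair_r(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def subset(self, snp_ids: Sequence[str]) -> "LDMatrix":
        """Restrict to the given SNPs, in the given order."""
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    def __repr__(self) -> str:
        return f"LDMatrix({len(self)} SNPs)"


@dataclass
class HarmonizedInstrumentSet:
    """Allele-aligned exposure/outcome effect vectors ready for estimation.

    All vectors share the order of ``snp_ids``; ``ld`` covers the same SNPs in
    the same order. ``outcome_scale`` is one of ``"log-odds"``, ``"SD"`` or
    ``"raw"`` and controls whether results are exponentiated into odds ratios.
    """

    snp_ids: list
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    ld: LDMatrix
    outcome_scale: str = "raw"
    eaf_exposure: Optional[np.ndarray] = None
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        k = len(self.snp_ids)
        if k < 1:
            raise FormatError("harmonized set must contain at least one SNP")
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            v = getattr(self, name)
            if v.shape != (k,):
                raise FormatError(f"{name} has shape {v.shape}, expected ({k},)")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise FormatError("standard errors must be strictly positive")
        if self.ld.snp_ids != list(self.snp_ids):
            raise FormatError("LD matrix order does not match snp_ids")
        if self.outcome_scale not in ("log-odds", "SD", "raw"):
            raise FormatError(f"unknown outcome scale {self.outcome_scale!r}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, snp_ids: Sequence[str]) -> "HarmonizedInstrumentSet":
        """Restrict to the given SNPs (order as given)."""
        idx = {s: i for i, s in enumerate(self.snp_ids)}
        sel = [idx[s] for s in snp_ids]
        return HarmonizedInstrumentSet(
            snp_ids=list(snp_ids),
            beta_exposure=self.beta_exposure[sel],
            se_exposure=self.se_exposure[sel],
            beta_outcome=self.beta_outcome[sel],
            se_outcome=self.se_outcome[sel],
            ld=self.ld.subset(snp_ids),
            outcome_scale=self.outcome_scale,
            eaf_exposure=None if self.eaf_exposure is None else self.eaf_exposure[sel],
        )
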