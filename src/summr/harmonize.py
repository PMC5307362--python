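"""Allele harmonization of outcome records onto exposure effect alleles.

Two-sample MR divides each SNP's outcome effect by its exposure effect, so
both must be expressed per copy of the *same* allele. Consortium files mix
allele orderings and strand conventions; this module aligns them:

* identical allele pair -> keep as is;
* swapped pair -> negate the outcome beta, complement its EAF;
* neither -> retry after flipping the outcome alleles to the opposite strand;
* still neither -> drop the SNP with reason ``allele_mismatch``.

Palindromic SNPs (A/T, C/G) cannot be strand-resolved from alleles alone and
are handled by policy. The default policy drops them when the outcome EAF is
missing or in the ambiguous band [0.42, 0.58]; outside the band, EAF
concordance between exposure and outcome decides whether the outcome record
is on the opposite strand (which for a palindromic pair is the same as an
allele swap).
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import EmptyInstrumentSetError
from .records import HarmonizedInstrumentSet, LDMatrix, SummaryRecord

logger = logging.getLogger("summr.harmonize")

#: (snp_id, reason_code) reason codes emitted by harmonize()
REASONS = (
    "missing_outcome",
    "missing_ld",
    "allele_mismatch",
    "palindromic_ambiguous",
    "palindromic_policy_strict",
)


class PalindromicPolicy:
    """How to treat A/T and C/G SNPs.

    mode:
      - ``"drop-ambiguous"`` (default): drop when outcome EAF is missing or in
        [ambiguity_low, ambiguity_high]; otherwise resolve strand by EAF
        concordance with the exposure EAF (falling back to allele labels when
        the exposure EAF is missing).
      - ``"strict"``: drop every palindromic SNP.
      - ``"keep"``: trust allele labels, never strand-correct palindromes.
    """

    def __init__(self, mode: str = "drop-ambiguous",
                 ambiguity_low: float = 0.42, ambiguity_high: float = 0.58):
        if mode not in ("drop-ambiguous", "strict", "keep"):
            raise ValueError(f"unknown palindromic policy {mode!r}")
        self.mode = mode
        self.ambiguity_low = ambiguity_low
        self.ambiguity_high = ambiguity_high

    def is_ambiguous(self, eaf: Optional[float]) -> bool:
        return eaf is None or self.ambiguity_low <= eaf <= self.ambiguity_high


DEFAULT_POLICY = PalindromicPolicy()


def _align_one(exp: SummaryRecord, out: SummaryRecord,
               policy: PalindromicPolicy) -> Tuple[Optional[SummaryRecord], Optional[str]]:
    """Return (aligned outcome record, None) or (None, drop reason)."""
    if exp.is_palindromic:
        if policy.mode == "strict":
            return None, "palindromic_policy_strict"
        # for a palindromic pair the strand flip is indistinguishable from an
        # allele swap, so only identical / swapped label patterns can occur
        if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
            aligned = out
        elif (out.other_allele, out.effect_allele) == (exp.effect_allele, exp.other_allele):
            aligned = out.flipped()
        else:
            return None, "allele_mismatch"
        if policy.mode == "keep":
            return aligned, None
        if policy.is_ambiguous(aligned.eaf):
            return None, "palindromic_ambiguous"
        # EAF discordance across 0.5 signals the outcome was reported on the
        # other strand: complement by flipping
        if exp.eaf is not None and (exp.eaf - 0.5) * (aligned.eaf - 0.5) < 0:
            aligned = aligned.flipped()
        return aligned, None

    for cand in (out, out.strand_flipped()):
        if (cand.effect_allele, cand.other_allele) == (exp.effect_allele, exp.other_allele):
            return cand, None
        if (cand.other_allele, cand.effect_allele) == (exp.effect_allele, exp.other_allele):
            return cand.flipped(), None
    return None, "allele_mismatch"


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    ld: Optional[LDMatrix] = None,
    palindromic_policy: PalindromicPolicy = DEFAULT_POLICY,
    outcome_scale: str = "raw",
) -> HarmonizedInstrumentSet:
    """Align outcome records to exposure effect alleles and assemble vectors.

    SNPs missing from the outcome list or from ``ld`` are dropped with a
    logged reason; output vectors follow the exposure order. ``ld=None`` uses
    an identity matrix (uncorrelated instruments). Raises
    :class:`EmptyInstrumentSetError` when nothing is retained.
    """
    out_by_id = {}
    for rec in outcome:
        out_by_id.setdefault(rec.snp_id, rec)

    kept_exp: List[SummaryRecord] = []
    kept_out: List[SummaryRecord] = []
    dropped: List[Tuple[str, str]] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            dropped.append((exp.snp_id, "missing_outcome"))
            continue
        if ld is not None and exp.snp_id not in ld:
            dropped.append((exp.snp_id, "missing_ld"))
            continue
        aligned, reason = _align_one(exp, out, palindromic_policy)
        if aligned is None:
            dropped.append((exp.snp_id, reason))
            continue
        kept_exp.append(exp)
        kept_out.append(aligned)
    for snp_id, reason in dropped:
        logger.info("harmonize dropped %s: %s", snp_id, reason)
    if not kept_exp:
        raise EmptyInstrumentSetError(
            f"no SNPs retained after harmonization ({len(dropped)} dropped)"
        )

    ids = [r.snp_id for r in kept_exp]
    sub_ld = ld.subset(ids) if ld is not None else LDMatrix.identity(ids)
    eafs = [r.eaf for r in kept_exp]
    return HarmonizedInstrumentSet(
        snp_ids=ids,
        beta_exposure=np.array([r.beta for r in kept_exp]),
        se_exposure=np.array([r.se for r in kept_exp]),
        beta_outcome=np.array([r.beta for r in kept_out]),
        se_outcome=np.array([r.se for r in kept_out]),
        ld=sub_ld,
        outcome_scale=outcome_scale,
        eaf_exposure=None if any(e is None for e in eafs) else np.array(eafs, dtype=float),
        dropped=dropped,
    )
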