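"""Packaged reference data for the serum-calcium MR analysis.

Two things live here:

* :func:`calcium_instruments` — the 13 genome-wide-significant serum-calcium
  SNPs (per-allele effects in mg/dl, SEs, MAFs, nearest genes) from the
  20,611-person calcium GWAS meta-analysis that motivates this package, four
  of which (rs7336933, rs17711722, rs17251221, rs10491003) are mutually
  near-independent and form the main-analysis instrument.
* :func:`build_candidate_panel` — a synthetic 128-SNP candidate panel wired
  so the selection pipeline reproduces the published accounting: 84 SNPs
  below genome-wide significance, 29 removed by high-LD pruning
  (r-squared >= 0.8), 2 excluded for known pleiotropy (bilirubin and
  parathyroid-hormone associations in the published analysis), leaving the
  13 instruments above.

The published source prints no per-SNP p-values and its supplementary LD
matrix is not redistributed, so the p-values here are reconstructed from
|beta|/SE (clamped just below 5e-8 where rounding of the printed SE would
contradict genome-wide significance) and the LD structure is synthetic: a
chromosome-3 cluster around the calcium-sensing-receptor locus with
moderate within-cluster correlation, independent SNPs elsewhere. Both are
labelled synthetic wherever they surface.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .records import LDMatrix, SummaryRecord
from .selection import CandidateSNP

#: Table of the 13 calcium instruments:
#: (rsid, nearest gene, effect allele, other allele, beta mg/dl, se, maf, main)
CALCIUM_TABLE: Tuple[Tuple[str, str, str, str, float, float, float, bool], ...] = (
    ("rs4306808", "FAM162A", "G", "C", 0.054, 0.0084, 0.1675, False),
    ("rs7336933", "DGKH/KIAA0564", "G", "A", 0.022, 0.0040, 0.1248, True),
    ("rs17711722", "VKORC1L1", "T", "C", 0.021, 0.0030, 0.4355, True),
    ("rs17267388", "PARP9", "A", "G", 0.036, 0.0059, 0.1300, False),
    ("rs1067", "WDR5B", "A", "G", 0.033, 0.0059, 0.1444, False),
    ("rs13095172", "CSTA;CASR", "T", "C", 0.028, 0.0046, 0.3524, False),
    ("rs11929034", "PARP9", "A", "G", 0.038, 0.0063, 0.1312, False),
    ("rs4491840", "CCDC58", "A", "G", 0.042, 0.0060, 0.1673, False),
    ("rs16832956", "CSTA;CASR", "G", "C", 0.044, 0.0053, 0.1641, False),
    ("rs17251221", "CASR", "G", "A", 0.061, 0.0063, 0.0942, True),
    ("rs10222633", "CASR", "G", "A", 0.030, 0.0042, 0.3852, False),
    ("rs10491003", "GATA3", "T", "C", 0.027, 0.0050, 0.1040, True),
    ("rs9864290", "CSTA", "C", "T", 0.028, 0.0047, 0.4453, False),
)

#: The four mutually near-independent main-analysis instruments.
MAIN_ANALYSIS_IDS: Tuple[str, ...] = tuple(
    row[0] for row in CALCIUM_TABLE if row[7]
)

#: First-stage sample size of the calcium GWAS meta-analysis.
CALCIUM_GWAS_N = 20611

_P_CLAMP = 4.5e-8  # keep reconstructed p just below genome-wide significance


def _reconstructed_p(beta: float, se: float) -> float:
    return min(2.0 * float(stats.norm.sf(abs(beta) / se)), _P_CLAMP)


def calcium_instruments() -> List[SummaryRecord]:
    """The 13 calcium SNPs as exposure SummaryRecords (beta in mg/dl).

    EAF is set to the printed MAF (the printed effect alleles are the minor
    alleles); p-values are synthetic reconstructions from |beta|/SE.
    """
    return [
        SummaryRecord(
            snp_id=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
            eaf=maf, pval=_reconstructed_p(beta, se), n=CALCIUM_GWAS_N,
        )
        for rsid, _gene, ea, oa, beta, se, maf, _main in CALCIUM_TABLE
    ]


# --- synthetic LD structure over the 13 instruments -------------------------

_CLUSTER_HUB = "rs17251221"
_CHR3_CLUSTER = tuple(
    row[0] for row in CALCIUM_TABLE if row[0] not in MAIN_ANALYSIS_IDS
)  # the 9 correlated non-main SNPs; all cluster with the CASR hub
_R_HUB = 0.30      # hub <-> cluster members (r^2 = 0.09: correlated, prune-safe)
_R_WITHIN = 0.25   # cluster member <-> cluster member


def _instrument_r(a: str, b: str) -> float:
    if a == b:
        return 1.0
    in_a = a in _CHR3_CLUSTER or a == _CLUSTER_HUB
    in_b = b in _CHR3_CLUSTER or b == _CLUSTER_HUB
    if in_a and in_b:
        return _R_HUB if _CLUSTER_HUB in (a, b) else _R_WITHIN
    return 0.0


def calcium_ld() -> LDMatrix:
    """Synthetic LD matrix over the 13 instruments.

    Mirrors the published qualitative structure — nine SNPs correlated in the
    chromosome-3 cluster around the calcium-sensing receptor, the four
    main-analysis SNPs mutually uncorrelated — without reproducing the
    original supplementary matrix.
    """
    ids = [row[0] for row in CALCIUM_TABLE]
    r = np.array([[_instrument_r(a, b) for b in ids] for a in ids])
    return LDMatrix(ids, r)


# --- the 128-SNP candidate panel --------------------------------------------

N_SUBTHRESHOLD = 84
N_PROXIES = 29
PLEIOTROPIC_SNPS: Tuple[Tuple[str, str, str, float, float, float], ...] = (
    # synthetic stand-ins for the two instruments excluded for pleiotropy
    # (published associations: bilirubin; parathyroid hormone)
    ("rs9990001", "A", "G", 0.050, 0.0070, 0.21),
    ("rs9990002", "C", "A", 0.040, 0.0060, 0.33),
)

_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


def build_candidate_panel(
    seed: int = 0,
) -> Tuple[List[CandidateSNP], LDMatrix, List[str]]:
    """Synthetic 128-SNP candidate panel for the selection pipeline.

    Returns (candidates, LD matrix, pleiotropy exclusion ids). The panel's
    category structure is fixed by construction — 84 sub-threshold SNPs, 29
    high-LD proxies each tagging a retained SNP at r = 0.95 with a larger
    p-value, 2 pleiotropy-flagged SNPs, 13 instruments — while ``seed`` only
    jitters incidental quantities (sub-threshold p-values, allele
    frequencies).
    """
    rng = np.random.default_rng(seed)
    instruments = calcium_instruments()
    pleio_records = [
        SummaryRecord(
            snp_id=rsid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
            eaf=maf, pval=_reconstructed_p(beta, se), n=CALCIUM_GWAS_N,
        )
        for rsid, ea, oa, beta, se, maf in PLEIOTROPIC_SNPS
    ]
    exclusion_ids = [r.snp_id for r in pleio_records]

    # proxies: r = 0.95 tags cycled over the 15 LD-prune survivors, p just
    # above the tag's (strictly below 5e-8 so they enter the pruning stage)
    tags = instruments + pleio_records
    proxies: List[SummaryRecord] = []
    proxy_tag: Dict[str, str] = {}
    per_tag_count: Dict[str, int] = {}
    for i in range(N_PROXIES):
        tag = tags[i % len(tags)]
        k = per_tag_count.get(tag.snp_id, 0)
        per_tag_count[tag.snp_id] = k + 1
        pval = tag.pval * (1.02 + 0.02 * k)
        assert pval < 5e-8
        z = float(stats.norm.isf(pval / 2.0))
        se = 0.005
        ea, oa = _ALLELE_CYCLE[i % 4]
        rsid = f"rs88{i + 1:05d}"
        proxies.append(
            SummaryRecord(
                snp_id=rsid, effect_allele=ea, other_allele=oa,
                beta=round(z * se, 6), se=se,
                eaf=round(float(rng.uniform(0.05, 0.5)), 4),
                pval=pval, n=CALCIUM_GWAS_N,
            )
        )
        proxy_tag[rsid] = tag.snp_id

    # sub-threshold background: suggestive but not genome-wide significant
    background: List[SummaryRecord] = []
    for i in range(N_SUBTHRESHOLD):
        pval = float(10 ** rng.uniform(math.log10(6e-8), math.log10(9e-6)))
        z = float(stats.norm.isf(pval / 2.0))
        se = 0.005
        ea, oa = _ALLELE_CYCLE[(i + 2) % 4]
        background.append(
            SummaryRecord(
                snp_id=f"rs77{i + 1:05d}", effect_allele=ea, other_allele=oa,
                beta=round(z * se, 6), se=se,
                eaf=round(float(rng.uniform(0.05, 0.5)), 4),
                pval=pval, n=CALCIUM_GWAS_N,
            )
        )

    records = instruments + pleio_records + proxies + background
    ids = [r.snp_id for r in records]

    def base_r(a: str, b: str) -> float:
        # LD among instruments + the two pleiotropic SNPs (loosely attached
        # to the chromosome-3 cluster, below the pruning threshold)
        if a == b:
            return 1.0
        pleio = set(exclusion_ids)
        if a in pleio or b in pleio:
            if a in pleio and b in pleio:
                return 0.15
            other = b if a in pleio else a
            in_cluster = other in _CHR3_CLUSTER or other == _CLUSTER_HUB
            return 0.20 if in_cluster else 0.0
        return _instrument_r(a, b)

    def pair_r(a: str, b: str) -> float:
        if a == b:
            return 1.0
        ta, tb = proxy_tag.get(a), proxy_tag.get(b)
        if ta and tb:
            return 0.90 if ta == tb else 0.9025 * base_r(ta, tb)
        if ta:
            return 0.95 if ta == b else 0.95 * base_r(ta, b)
        if tb:
            return 0.95 if tb == a else 0.95 * base_r(a, tb)
        if a.startswith("rs77") or b.startswith("rs77"):
            return 0.0
        return base_r(a, b)

    r = np.array([[pair_r(a, b) for b in ids] for a in ids])
    candidates = [
        CandidateSNP.from_record(rec, pleiotropy_flag=rec.snp_id in exclusion_ids)
        for rec in records
    ]
    return candidates, LDMatrix(ids, r), exclusion_ids


def write_candidate_panel(directory, seed: int = 0) -> Dict[str, str]:
    """Write the candidate panel as the three pipeline input files.

    Returns {"summary": ..., "ld": ..., "exclusion": ...} paths.
    """
    import os

    from .io import write_ld_matrix, write_summary_table

    candidates, ld, exclusion = build_candidate_panel(seed)
    paths = {
        "summary": os.path.join(directory, "candidates.tsv"),
        "ld": os.path.join(directory, "ld.tsv"),
        "exclusion": os.path.join(directory, "pleiotropy_exclusions.txt"),
    }
    write_summary_table(candidates, paths["summary"])
    write_ld_matrix(ld, paths["ld"])
    with open(paths["exclusion"], "w") as fh:
        fh.write("\n".join(exclusion) + "\n")
    return paths


def make_synthetic_outcome(
    exposure: Sequence[SummaryRecord],
    b: float,
    seed: int,
    se_outcome: float = 0.01,
    n: int = 80000,
) -> List[SummaryRecord]:
    """Summary-level synthetic outcome records consistent with an exposure set.

    Draws beta_Yj ~ normal(b * beta_Xj, se_outcome) with matching alleles, so
    the pair harmonizes trivially and the true causal slope is ``b``. A quick
    way to exercise the pipeline against the packaged instruments without
    individual-level simulation.
    """
    rng = np.random.default_rng(seed)
    return [
        SummaryRecord(
            snp_id=r.snp_id, effect_allele=r.effect_allele,
            other_allele=r.other_allele,
            beta=float(rng.normal(b * r.beta, se_outcome)), se=se_outcome,
            eaf=r.eaf, pval=None, n=n,
        )
        for r in exposure
    ]
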