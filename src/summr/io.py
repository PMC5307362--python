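"""Readers and writers for delimited summary-statistics tables and LD matrices.

The canonical column set is ``snp, effect_allele, other_allele, beta, se,
eaf, pval, n``; a ``column_map`` renames source columns onto it so consortium
files with arbitrary headers can be ingested without editing. Both tab- and
comma-delimited files are accepted (the delimiter is sniffed from the header
unless given). Dropped rows are logged with machine-readable reason codes.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, FormatError, RowError
from .records import LDMatrix, SummaryRecord

logger = logging.getLogger("summr.io")

#: canonical field -> whether it is mandatory
CANONICAL_COLUMNS = {
    "snp": True,
    "effect_allele": True,
    "other_allele": True,
    "beta": True,
    "se": True,
    "eaf": False,
    "pval": False,
    "n": False,
}


def _sniff_delimiter(path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_summary_table(
    path,
    column_map: Optional[Dict[str, str]] = None,
    delimiter: Optional[str] = None,
    on_invalid: str = "raise",
) -> List[SummaryRecord]:
    """Read a delimited summary-statistics file into SummaryRecords.

    Parameters
    ----------
    path : str or Path
        Tab- or comma-delimited text file with a header row.
    column_map : dict, optional
        Maps canonical field names (``snp``, ``effect_allele``, ...) to the
        column names used in the file. Unmapped canonical names are looked up
        verbatim.
    delimiter : str, optional
        Field delimiter; sniffed from the header when omitted.
    on_invalid : {"raise", "drop"}
        What to do with rows that violate record invariants (e.g. se <= 0):
        raise a :class:`RowError` carrying the line number, or drop the row
        and log its reason code.

    Returns
    -------
    list of SummaryRecord, one per retained data row, alleles upper-cased.
    """
    column_map = dict(column_map or {})
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]

    source_for: Dict[str, Optional[str]] = {}
    for canon, mandatory in CANONICAL_COLUMNS.items():
        src = column_map.get(canon, canon)
        if src in df.columns:
            source_for[canon] = src
        elif mandatory:
            raise ConfigError(
                f"{path}: mandatory column {canon!r} (source {src!r}) not in header "
                f"{list(df.columns)}"
            )
        else:
            source_for[canon] = None

    def parse_float(raw: str, field: str, line: int, optional: bool) -> Optional[float]:
        raw = raw.strip()
        if raw in ("", "NA", "NaN", "nan", "."):
            if optional:
                return None
            raise RowError(line, "missing_value", f"field {field}")
        try:
            return float(raw)
        except ValueError:
            raise RowError(line, "unparseable_numeric", f"field {field} = {raw!r}") from None

    records: List[SummaryRecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # 1-based, after the header
        row = dict(zip(df.columns, row))
        try:
            se = parse_float(row[source_for["se"]], "se", line, optional=False)
            if se is None or se <= 0 or not math.isfinite(se):
                raise RowError(line, "nonpositive_se", f"se = {se}")
            eaf = n = pval = None
            if source_for["eaf"]:
                eaf = parse_float(row[source_for["eaf"]], "eaf", line, optional=True)
            if source_for["pval"]:
                pval = parse_float(row[source_for["pval"]], "pval", line, optional=True)
            if source_for["n"]:
                n_f = parse_float(row[source_for["n"]], "n", line, optional=True)
                n = None if n_f is None else int(round(n_f))
            try:
                rec = SummaryRecord(
                    snp_id=row[source_for["snp"]].strip(),
                    effect_allele=row[source_for["effect_allele"]].strip().upper(),
                    other_allele=row[source_for["other_allele"]].strip().upper(),
                    beta=parse_float(row[source_for["beta"]], "beta", line, optional=False),
                    se=se,
                    eaf=eaf,
                    pval=pval,
                    n=n,
                )
            except FormatError as exc:
                raise RowError(line, "invalid_record", str(exc)) from None
        except RowError as exc:
            if on_invalid == "drop":
                logger.warning("dropped row: %s", exc)
                continue
            raise
        records.append(rec)
    return records


def write_summary_table(records: Sequence[SummaryRecord], path, delimiter: str = "\t") -> None:
    """Write records in the canonical column layout at full float precision."""
    def fmt(x):
        return "" if x is None else repr(x) if isinstance(x, float) else str(x)

    with open(path, "w") as fh:
        fh.write(delimiter.join(CANONICAL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                delimiter.join(
                    [r.snp_id, r.effect_allele, r.other_allele,
                     repr(float(r.beta)), repr(float(r.se)),
                     fmt(r.eaf), fmt(r.pval), fmt(r.n)]
                )
                + "\n"
            )


def load_ld_matrix(path, delimiter: Optional[str] = None, tol: float = 1e-8) -> LDMatrix:
    """Load a square LD correlation table with rsID header row and first column.

    Symmetry is enforced within ``tol`` and the matrix exactly symmetrized;
    non-square tables, |r| > 1 entries or row/column id mismatches raise
    :class:`FormatError`.
    """
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    ids_cols = [str(c).strip() for c in df.columns]
    ids_rows = [str(i).strip() for i in df.index]
    if ids_cols != ids_rows:
        raise FormatError(f"{path}: LD row ids do not match column ids")
    try:
        r = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric LD entry ({exc})") from None
    return LDMatrix(ids_rows, r, tol=tol)


def write_ld_matrix(ld: LDMatrix, path, delimiter: str = "\t") -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep=delimiter, float_format="%.10g"
    )


def empirical_ld(snp_ids: Sequence[str], genotypes: np.ndarray) -> LDMatrix:
    """Sample LD correlation matrix from a genotype dosage matrix (n x K)."""
    r = np.corrcoef(np.asarray(genotypes, dtype=float), rowvar=False)
    r = np.atleast_2d(r)
    return LDMatrix(list(snp_ids), 0.5 * (r + r.T))
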