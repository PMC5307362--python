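import numpy as np
import pytest

from summr import (
    HarmonizedInstrumentSet,
    LDMatrix,
    SummaryRecord,
    calcium_instruments,
    write_summary_table,
)


@pytest.fixture
def table1_records():
    return calcium_instruments()


@pytest.fixture
def table1_file(tmp_path, table1_records):
    path = tmp_path / "calcium.tsv"
    write_summary_table(table1_records, path)
    return path


def make_record(snp="rs1", ea="A", oa="G", beta=0.05, se=0.01, eaf=0.3,
                pval=1e-9, n=20000):
    return SummaryRecord(snp_id=snp, effect_allele=ea, other_allele=oa,
                         beta=beta, se=se, eaf=eaf, pval=pval, n=n)


def make_hset(bx, by, sy, sx=None, rho=None, scale="raw"):
    """Small harmonized set from raw vectors (identity LD unless rho given)."""
    bx = np.asarray(bx, float)
    k = bx.size
    ids = [f"rs{i+1}" for i in range(k)]
    ld = LDMatrix(ids, np.eye(k) if rho is None else np.asarray(rho, float))
    return HarmonizedInstrumentSet(
        snp_ids=ids,
        beta_exposure=bx,
        se_exposure=np.full(k, 0.01) if sx is None else np.asarray(sx, float),
        beta_outcome=np.asarray(by, float),
        se_outcome=np.asarray(sy, float),
        ld=ld,
        outcome_scale=scale,
    )


@pytest.fixture
def hset_factory():
    return make_hset
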