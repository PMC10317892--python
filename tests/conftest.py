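import numpy as np
import pytest

from targetmr.gwas_io import LDMatrix, SummaryStatRecord, SummaryStatsTable


def record(vid="rs1", chrom="1", pos=1000, ea="A", nea="G", eaf=0.3,
           beta=0.05, se=0.01, pval=1e-9, n=10_000, n_cases=None):
    return SummaryStatRecord(vid, chrom, pos, ea, nea, eaf, beta, se, pval,
                             n, n_cases)


@pytest.fixture
def small_table():
    recs = [
        record("rs1", pos=1_000, beta=0.08, se=0.01, pval=1e-20),
        record("rs2", pos=2_000, beta=0.06, se=0.01, pval=1e-10),
        record("rs3", pos=3_000, beta=0.05, se=0.01, pval=1e-9),
    ]
    return SummaryStatsTable("trait", "quantitative", recs)


@pytest.fixture
def identity_ld():
    def _make(ids):
        return LDMatrix(list(ids), np.eye(len(ids)))
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
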