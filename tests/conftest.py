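import numpy as np
import pandas as pd
import pytest

from pqtlscreen.datasets import load_coloc_top_hits, load_mr_top_hits
from pqtlscreen.sumstats import SUMSTAT_COLUMNS, SumstatsTable


def make_sumstats_df(rows):
    """Build a summary-statistics DataFrame from (id, chrom, pos, ea, oa, eaf, beta, se, p, n)."""
    return pd.DataFrame(rows, columns=SUMSTAT_COLUMNS)


@pytest.fixture
def mr_top_hits():
    return load_mr_top_hits()


@pytest.fixture
def coloc_top_hits():
    return load_coloc_top_hits()


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture
def simple_exposure():
    df = make_sumstats_df([
        ("rs1", "1", 1_000_000, "A", "G", 0.30, 0.50, 0.02, 1e-9, 3000),
        ("rs2", "1", 1_050_000, "C", "T", 0.10, 0.20, 0.05, 1e-4, 3000),
        ("rs3", "1", 1_100_000, "A", "T", 0.50, 0.10, 0.04, 0.01, 3000),
    ])
    return SumstatsTable("GENE1", "quantitative", df)


@pytest.fixture
def simple_outcome():
    df = make_sumstats_df([
        ("rs1", "1", 1_000_000, "A", "G", 0.31, 0.20, 0.04, 1e-6, 50_000),
        ("rs2", "1", 1_050_000, "T", "C", 0.89, -0.08, 0.03, 0.008, 50_000),
        ("rs3", "1", 1_100_000, "A", "T", 0.49, 0.02, 0.02, 0.3, 50_000),
        ("rs4", "1", 1_200_000, "G", "C", 0.20, 0.01, 0.02, 0.6, 50_000),
    ])
    return SumstatsTable("outcome", "binary", df, case_n=2860, control_n=270_964)
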