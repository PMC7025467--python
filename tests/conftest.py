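import numpy as np
import pandas as pd
import pytest

from admixkit.genotype_io import MISSING, AlleleFreqTable, GenotypeMatrix


def make_snps(n, chrom=1, spacing=100_000, start=100_000):
    """Evenly spaced SNP map on one chromosome."""
    return pd.DataFrame({
        "id": [f"snp{i}" for i in range(n)],
        "chrom": chrom,
        "pos": start + spacing * np.arange(n),
        "a1": "A", "a2": "B",
    })


@pytest.fixture
def small_genotypes():
    """3 samples x 4 SNPs with one missing call."""
    calls = np.array([
        [0, 1, 2, 0],
        [1, MISSING, 2, 0],
        [2, 1, 0, 1],
    ], dtype=np.int8)
    return GenotypeMatrix(["s1", "s2", "s3"], make_snps(4), calls)


@pytest.fixture
def small_pop_map():
    return {"s1": "popA", "s2": "popA", "s3": "popB"}


@pytest.fixture
def hand_freq_table():
    """6-SNP, 4-population table with hand-enumerable counts."""
    counts = np.array([
        [2, 4, 0, 6, 3, 1],
        [1, 3, 2, 5, 4, 0],
        [0, 2, 4, 4, 2, 2],
        [3, 1, 1, 3, 1, 3],
    ])
    totals = np.full((4, 6), 6)
    return AlleleFreqTable(["P1", "P2", "P3", "P4"], make_snps(6),
                           counts, totals)
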