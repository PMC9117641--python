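import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from strvar.catalog import GeneModel, StrLocus


@pytest.fixture
def toy_gene():
    """Plus-strand gene at 5000-15000 with three exons and one UTR island."""
    return GeneModel(
        gene_id="GA",
        chrom="chr1",
        strand="+",
        tx_start=5_000,
        tx_end=15_000,
        exons=((5_000, 5_600), (9_300, 9_900), (14_400, 15_000)),
        utr=((5_600, 5_800),),
    )


@pytest.fixture
def toy_gene_minus(toy_gene):
    return GeneModel(
        gene_id="GB",
        chrom="chr1",
        strand="-",
        tx_start=toy_gene.tx_start,
        tx_end=toy_gene.tx_end,
        exons=toy_gene.exons,
        utr=toy_gene.utr,
    )


def make_locus(locus_id, start, end, motif="CAG", chrom="chr1", **kw):
    return StrLocus(locus_id=locus_id, chrom=chrom, start=start, end=end,
                    motif=motif, **kw)


@pytest.fixture
def small_reads():
    """Two samples x two loci; one cell below the 8x coverage floor."""
    rows = []
    rows += [("s1", "L1", c) for c in [18, 20, 15, 15, 14, 12, 12, 11]]
    rows += [("s1", "L2", c) for c in [10] * 9]
    rows += [("s2", "L1", c) for c in [7, 7, 8, 8, 9, 9, 10, 10, 11]]
    rows += [("s2", "L2", c) for c in [30, 29, 28, 27, 26, 25, 24]]  # only 7 reads
    return pd.DataFrame(rows, columns=["sample_id", "locus_id", "repeat_count"])


@pytest.fixture
def small_catalog():
    return [make_locus("L1", 100, 130), make_locus("L2", 500, 530, motif="ACGT")]
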