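import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from lncpath.catalog import GeneCatalog, GeneRecord, GenomicInterval
from lncpath.de import ExpressionMatrix


def make_gene(gene_id, exons, chrom="chr1", strand="+", biotype="lncRNA"):
    """Gene from a list of (start, end) exon tuples."""
    return GeneRecord(
        gene_id=gene_id,
        biotype=biotype,
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )


def random_catalog(n_genes, rng, chrom_count=3, prefix="G"):
    """Random genes with 1-3 exons; overlaps allowed."""
    catalog = GeneCatalog()
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, chrom_count + 1)}"
        start = int(rng.integers(1, 100_000))
        exons = []
        pos = start
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(50, 400))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(1, 300))
        catalog.add(make_gene(f"{prefix}{i:04d}", exons, chrom=chrom))
    return catalog


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix(rng):
    """60 genes x 24 samples, two groups, no signal."""
    counts = rng.poisson(50, size=(60, 24))
    genes = [f"G{i:03d}" for i in range(60)]
    samples = [f"S{i:02d}" for i in range(24)]
    meta = pd.DataFrame(
        {
            "condition": ["les"] * 12 + ["ctl"] * 12,
            "group": ["les"] * 12 + ["ctl"] * 12,
            "sex": list(np.where(rng.random(24) < 0.5, "F", "M")),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        sample_metadata=meta,
    )
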