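"""Shared fixtures: small deterministic gene models and study configs."""

import numpy as np
import pandas as pd
import pytest

from loopgene.annotation import GeneModel
from loopgene.config import SimConfig


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    """Three hand-placed genes on one chromosome.

    gA: '+' strand, body [10_000, 30_000), 3 exons (intron 2 spans
        [16_000, 24_000)), with UTR stubs.
    gB: '-' strand, body [50_000, 70_000), single exon.
    gC: '+' strand, body [31_000, 40_000), single exon (downstream of gA).
    """
    return [
        GeneModel(
            gene_id="gA", symbol="GA", chrom="chr1", strand="+",
            start=10_000, end=30_000,
            exons=((10_000, 14_000), (15_000, 16_000), (24_000, 30_000)),
            five_utr=((10_000, 10_150),), three_utr=((29_850, 30_000),),
        ),
        GeneModel(
            gene_id="gB", symbol="GB", chrom="chr1", strand="-",
            start=50_000, end=70_000, exons=((50_000, 70_000),),
        ),
        GeneModel(
            gene_id="gC", symbol="GC", chrom="chr1", strand="+",
            start=31_000, end=40_000, exons=((31_000, 40_000),),
        ),
    ]


@pytest.fixture
def small_config() -> SimConfig:
    """Fast generator settings for unit tests (not the reference conditions)."""
    return SimConfig(
        seed=1,
        n_haplotypes=200,
        n_snps_per_locus=50,
        n_loci=2,
        n_individuals=500,
        chrom_length=1_000_000,
        sequencing_depth=200_000,
        n_planted_loops=3,
        loop_gap_range=(20_000, 200_000),
        n_genes=20,
        n_tumor=5,
        n_normal=5,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_loops(rows: list[tuple], source: str = "CL1") -> pd.DataFrame:
    """Loop table from (chrom, bin1, bin2) bin-index triples at 5 kb."""
    res = 5_000
    recs = []
    for chrom, b1, b2 in rows:
        recs.append(
            {
                "chrom1": chrom, "start1": b1 * res, "end1": (b1 + 1) * res,
                "chrom2": chrom, "start2": b2 * res, "end2": (b2 + 1) * res,
                "count": 10, "expected": 2.0, "p_value": 1e-8, "q_value": 1e-6,
                "distance": (b2 - b1) * res, "source": source,
            }
        )
    return pd.DataFrame(recs)
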