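"""Promoter windows, functional classification of loop anchors, anchor->gene lookup.

Loop anchors (5 kb bins) are assigned to one of seven mutually exclusive
functional categories by precedence: promoter > 5'UTR > 3'UTR > exon > intron
> downstream > distal intergenic.  Promoter-associated loops (at least one
promoter anchor) are further split into promoter-promoter, promoter-distal
intergenic, promoter-intron and promoter-other (UTR, exon, gene downstream)
by the category of the non-promoter anchor.

All coordinates are half-open, 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

ANCHOR_CATEGORIES = (
    "promoter",
    "five_utr",
    "three_utr",
    "exon",
    "intron",
    "downstream",
    "distal_intergenic",
)

LOOP_CATEGORIES = (
    "promoter_promoter",
    "promoter_distal_intergenic",
    "promoter_intron",
    "promoter_other",
    "non_promoter",
)

#: bp past the gene 3' end still counted as "downstream" of the gene.
DOWNSTREAM_EXTENT = 3_000

#: default promoter half-windows around the TSS (bp).
PROMOTER_UPSTREAM = 2_500
PROMOTER_DOWNSTREAM = 2_500


@dataclass(frozen=True)
class GeneModel:
    """A gene body with exon structure on one strand.

    ``start``/``end`` are half-open 0-based; the TSS is ``start`` on '+' and
    ``end - 1`` on '-'.  UTR intervals are optional (empty when the annotation
    carries no CDS information).
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    five_utr: tuple[tuple[int, int], ...] = ()
    three_utr: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def promoter_window(
    gene: GeneModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    chrom_size: int | None = None,
) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    Upstream extends against the direction of transcription.  Returns a
    half-open (start, end) interval.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("promoter window extents must be non-negative")
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - upstream, tss + downstream
    else:
        lo, hi = tss - downstream, tss + upstream
    lo = max(lo, 0)
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    return lo, hi


def promoter_windows(
    genes: list[GeneModel],
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Promoter windows for a gene list as a (chrom, start, end, gene_id) frame."""
    rows = []
    for g in genes:
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        lo, hi = promoter_window(g, upstream, downstream, size)
        rows.append((g.chrom, lo, hi, g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def _downstream_interval(gene: GeneModel, extent: int) -> tuple[int, int]:
    """Interval immediately past the gene 3' end, strand-aware."""
    if gene.strand == "+":
        return gene.end, gene.end + extent
    return max(gene.start - extent, 0), gene.start


class GenomeAnnotation:
    """Indexed view of a gene set supporting anchor classification and lookup.

    Builds one interval tree per chromosome and feature class so that anchor
    queries are O(log n).  Deterministic under gene reordering: query results
    are sorted, and classification depends only on which feature classes the
    anchor overlaps.
    """

    def __init__(
        self,
        genes: list[GeneModel],
        upstream: int = PROMOTER_UPSTREAM,
        downstream: int = PROMOTER_DOWNSTREAM,
        downstream_extent: int = DOWNSTREAM_EXTENT,
        chrom_sizes: dict[str, int] | None = None,
    ):
        if upstream < 0 or downstream < 0:
            raise ValueError("promoter window extents must be non-negative")
        self.genes = list(genes)
        self.by_id = {g.gene_id: g for g in self.genes}
        self.upstream = upstream
        self.downstream = downstream
        self._trees: dict[str, dict[str, IntervalTree]] = {}

        def _add(feature: str, chrom: str, lo: int, hi: int, gene_id: str) -> None:
            if hi <= lo:
                return
            self._trees.setdefault(chrom, {}).setdefault(feature, IntervalTree())
            self._trees[chrom][feature].addi(lo, hi, gene_id)

        for g in self.genes:
            size = chrom_sizes.get(g.chrom) if chrom_sizes else None
            plo, phi = promoter_window(g, upstream, downstream, size)
            _add("promoter", g.chrom, plo, phi, g.gene_id)
            _add("body", g.chrom, g.start, g.end, g.gene_id)
            for s, e in g.exons:
                _add("exon", g.chrom, s, e, g.gene_id)
            for s, e in g.five_utr:
                _add("five_utr", g.chrom, s, e, g.gene_id)
            for s, e in g.three_utr:
                _add("three_utr", g.chrom, s, e, g.gene_id)
            dlo, dhi = _downstream_interval(g, downstream_extent)
            _add("downstream", g.chrom, dlo, dhi, g.gene_id)

    def _hits(self, feature: str, chrom: str, start: int, end: int) -> set[str]:
        trees = self._trees.get(chrom)
        if not trees or feature not in trees:
            return set()
        return {iv.data for iv in trees[feature].overlap(start, end)}

    def classify_anchor(self, chrom: str, start: int, end: int) -> str:
        """Functional category of an anchor interval, by feature precedence."""
        if chrom not in self._trees:
            logger.warning("anchor on unannotated chromosome %s", chrom)
            return "distal_intergenic"
        for feature in ("promoter", "five_utr", "three_utr", "exon"):
            if self._hits(feature, chrom, start, end):
                return feature
        # any remaining body overlap is intronic sequence
        if self._hits("body", chrom, start, end):
            return "intron"
        if self._hits("downstream", chrom, start, end):
            return "downstream"
        return "distal_intergenic"

    def genes_at(self, chrom: str, start: int, end: int, mode: str = "promoter") -> list[str]:
        """Gene ids whose promoter window (or body) overlaps the anchor, sorted."""
        if mode not in ("promoter", "body"):
            raise ValueError(f"mode must be 'promoter' or 'body', got {mode!r}")
        return sorted(self._hits(mode, chrom, start, end))


def classify_anchor(anchor: tuple[str, int, int], genes, **kwargs) -> str:
    """Classify one anchor; ``genes`` is a gene list or a GenomeAnnotation."""
    ann = genes if isinstance(genes, GenomeAnnotation) else GenomeAnnotation(genes, **kwargs)
    return ann.classify_anchor(*anchor)


def loop_category(cat1: str, cat2: str) -> str:
    """Loop category from its two anchor categories.

    Non-promoter loops keep their own class; otherwise the category is set by
    the non-promoter anchor, with UTR/exon/downstream collapsed to 'other'.
    """
    for c in (cat1, cat2):
        if c not in ANCHOR_CATEGORIES:
            raise ValueError(f"unknown anchor category {c!r}")
    if "promoter" not in (cat1, cat2):
        return "non_promoter"
    if cat1 == cat2 == "promoter":
        return "promoter_promoter"
    other = cat2 if cat1 == "promoter" else cat1
    if other == "distal_intergenic":
        return "promoter_distal_intergenic"
    if other == "intron":
        return "promoter_intron"
    return "promoter_other"


def classify_loop(loop_row, ann: GenomeAnnotation) -> str:
    """Loop category of one BEDPE-style row with anchor columns."""
    c1 = ann.classify_anchor(loop_row["chrom1"], loop_row["start1"], loop_row["end1"])
    c2 = ann.classify_anchor(loop_row["chrom2"], loop_row["start2"], loop_row["end2"])
    return loop_category(c1, c2)


def classify_loops(loops: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Annotate a loop table with anchor categories and the loop category."""
    out = loops.copy()
    out["anchor1_category"] = [
        ann.classify_anchor(r.chrom1, r.start1, r.end1) for r in loops.itertuples()
    ]
    out["anchor2_category"] = [
        ann.classify_anchor(r.chrom2, r.start2, r.end2) for r in loops.itertuples()
    ]
    out["loop_category"] = [
        loop_category(a, b)
        for a, b in zip(out["anchor1_category"], out["anchor2_category"])
    ]
    return out


def genes_at_anchor(anchor: tuple[str, int, int], genes, mode: str = "promoter", **kwargs) -> list[str]:
    """Gene ids at an anchor interval (promoter-window or body overlap)."""
    ann = genes if isinstance(genes, GenomeAnnotation) else GenomeAnnotation(genes, **kwargs)
    return ann.genes_at(*anchor, mode=mode)


def category_fractions(classified_loops: pd.DataFrame) -> pd.Series:
    """Fraction of loops per loop category (sums to 1 over all loops)."""
    frac = classified_loops["loop_category"].value_counts(normalize=True)
    return frac.reindex(LOOP_CATEGORIES, fill_value=0.0)
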