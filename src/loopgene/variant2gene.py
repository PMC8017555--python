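"""Credible-variant -> target-gene mapping through chromatin loops.

A credible variant (CV) lying inside one anchor of a significant loop is
linked to every gene annotated at the opposite anchor; the link distance is
|variant position - target TSS|.  Links can be filtered by open-chromatin
peak sets, compared against eQTL and proximal target assignments, and
summarized per GWAS locus (distinct CV counts, sorted target gene lists,
distance statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import GenomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "map_cvs_to_targets",
    "filter_by_open_chromatin",
    "proximal_targets",
    "TargetSetComparison",
    "compare_target_sets",
    "LocusSummary",
    "summarize_loci",
    "load_published_locus_table",
]

LINK_COLUMNS = [
    "variant_id", "chrom", "pos", "locus_id", "gene_id",
    "loop_id", "source", "distance", "anchor_distance",
]


def map_cvs_to_targets(
    cvs: pd.DataFrame,
    loops: pd.DataFrame,
    ann: GenomeAnnotation,
    mode: str = "promoter",
) -> pd.DataFrame:
    """Assign target genes to credible variants through loop anchors.

    ``cvs`` needs columns variant_id, chrom, pos (1-based point) and
    optionally locus_id; ``loops`` is a BEDPE-style frame with half-open
    anchors and a ``source`` label.  A variant whose position falls in one
    anchor yields one link per gene at the opposite anchor (promoter-window
    or body overlap per ``mode``), deduplicated on (variant, gene, loop).
    ``distance`` is |pos - TSS|; ``anchor_distance`` is the loop's
    anchor-midpoint separation, kept as an alternative measure.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, row in loops.iterrows():
        loop_id = f"loop{idx}"
        trees.setdefault(row["chrom1"], IntervalTree()).addi(
            row["start1"], row["end1"], (idx, loop_id, 1)
        )
        trees.setdefault(row["chrom2"], IntervalTree()).addi(
            row["start2"], row["end2"], (idx, loop_id, 2)
        )
    rows = []
    for cv in cvs.itertuples():
        tree = trees.get(cv.chrom)
        if tree is None:
            continue
        pos0 = cv.pos - 1  # 1-based point -> 0-based coordinate
        for iv in tree.at(pos0):
            idx, loop_id, side = iv.data
            loop = loops.loc[idx]
            other = ("chrom2", "start2", "end2") if side == 1 else ("chrom1", "start1", "end1")
            anchor = (loop[other[0]], int(loop[other[1]]), int(loop[other[2]]))
            mid1 = (loop["start1"] + loop["end1"]) / 2
            mid2 = (loop["start2"] + loop["end2"]) / 2
            for gene_id in ann.genes_at(*anchor, mode=mode):
                gene = ann.by_id[gene_id]
                rows.append(
                    {
                        "variant_id": cv.variant_id,
                        "chrom": cv.chrom,
                        "pos": cv.pos,
                        "locus_id": getattr(cv, "locus_id", ""),
                        "gene_id": gene_id,
                        "loop_id": loop_id,
                        "source": loop.get("source", ""),
                        "distance": abs(int(cv.pos) - 1 - gene.tss),
                        "anchor_distance": abs(int(mid2 - mid1)),
                    }
                )
    links = pd.DataFrame(rows, columns=LINK_COLUMNS)
    links = links.drop_duplicates(subset=["variant_id", "gene_id", "loop_id"])
    return links.sort_values(["variant_id", "gene_id", "loop_id"]).reset_index(drop=True)


def filter_by_open_chromatin(
    table: pd.DataFrame,
    peak_sets: list[pd.DataFrame] | dict[str, pd.DataFrame],
    require_all: bool = True,
) -> pd.DataFrame:
    """Keep rows whose variant position lies in a peak of every (or any) set.

    Works on any frame with ``chrom`` and ``pos`` columns (CV tables or link
    tables).  The output is always a subset of the input; adding peaks can
    only grow it (monotonicity).
    """
    if isinstance(peak_sets, dict):
        peak_sets = list(peak_sets.values())
    if not peak_sets:
        raise ValueError("need at least one peak set")
    hits = []
    for peaks in peak_sets:
        if len(peaks) == 0 and require_all:
            logger.warning("empty peak set with require_all=True: no variants retained")
        tree: dict[str, IntervalTree] = {}
        for p in peaks.itertuples():
            tree.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
        in_set = np.array(
            [
                bool(tree.get(r.chrom) and tree[r.chrom].at(r.pos - 1))
                for r in table.itertuples()
            ],
            dtype=bool,
        ) if len(table) else np.zeros(0, dtype=bool)
        hits.append(in_set)
    stacked = np.vstack(hits) if hits else np.zeros((0, len(table)), dtype=bool)
    keep = stacked.all(axis=0) if require_all else stacked.any(axis=0)
    return table[keep].reset_index(drop=True)


def proximal_targets(cvs: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Baseline variant->gene assignment: containing gene body, else nearest TSS.

    Ties at equal TSS distance go to the smaller genomic coordinate, then the
    lexicographically smaller gene id.  Variants on gene-free chromosomes are
    logged and omitted.
    """
    by_chrom: dict[str, list] = {}
    for g in ann.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for cv in cvs.itertuples():
        genes = by_chrom.get(cv.chrom)
        if not genes:
            logger.info("variant %s on gene-free chromosome %s", cv.variant_id, cv.chrom)
            continue
        pos0 = cv.pos - 1
        inside = sorted(
            (g for g in genes if g.start <= pos0 < g.end),
            key=lambda g: (g.start, g.gene_id),
        )
        if inside:
            chosen, dist = inside[0], 0
        else:
            chosen = min(genes, key=lambda g: (abs(pos0 - g.tss), g.tss, g.gene_id))
            dist = abs(pos0 - chosen.tss)
        rows.append(
            {
                "variant_id": cv.variant_id,
                "chrom": cv.chrom,
                "pos": cv.pos,
                "gene_id": chosen.gene_id,
                "distance": dist,
            }
        )
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "gene_id", "distance"])


@dataclass(frozen=True)
class TargetSetComparison:
    """Set algebra over HiChIP / eQTL / proximal target gene sets."""

    n_hichip: int
    n_eqtl: int
    n_proximal: int
    overlap_hichip_eqtl: int
    overlap_hichip_proximal: int
    overlap_eqtl_proximal: int
    triple_overlap: int
    fold_vs_eqtl: float | None
    fold_vs_proximal: float | None
    triple_genes: tuple[str, ...]

    def to_dict(self) -> dict:
        d = {
            "n_hichip": self.n_hichip,
            "n_eqtl": self.n_eqtl,
            "n_proximal": self.n_proximal,
            "overlap_hichip_eqtl": self.overlap_hichip_eqtl,
            "overlap_hichip_proximal": self.overlap_hichip_proximal,
            "overlap_eqtl_proximal": self.overlap_eqtl_proximal,
            "triple_overlap": self.triple_overlap,
            "fold_vs_eqtl": None if self.fold_vs_eqtl is None else round(self.fold_vs_eqtl, 1),
            "fold_vs_proximal": (
                None if self.fold_vs_proximal is None else round(self.fold_vs_proximal, 1)
            ),
            "triple_genes": list(self.triple_genes),
        }
        return d


def compare_target_sets(hichip, eqtl, proximal) -> TargetSetComparison:
    """Pairwise/triple overlaps and fold ratios of three target gene sets.

    Gene symbols are case-normalized before comparison.  Fold ratios
    |HiChIP|/|other| are reported to one decimal in :meth:`to_dict` and are
    undefined (None) against an empty set.
    """
    h = {str(g).upper() for g in hichip}
    e = {str(g).upper() for g in eqtl}
    p = {str(g).upper() for g in proximal}
    return TargetSetComparison(
        n_hichip=len(h),
        n_eqtl=len(e),
        n_proximal=len(p),
        overlap_hichip_eqtl=len(h & e),
        overlap_hichip_proximal=len(h & p),
        overlap_eqtl_proximal=len(e & p),
        triple_overlap=len(h & e & p),
        fold_vs_eqtl=(len(h) / len(e)) if e and h else None,
        fold_vs_proximal=(len(h) / len(p)) if p and h else None,
        triple_genes=tuple(sorted(h & e & p)),
    )


@dataclass(frozen=True)
class LocusSummary:
    """Per-locus roll-up of variant->gene links (the locus-table surface)."""

    locus_id: str
    cv_count: int
    target_genes: tuple[str, ...]
    median_distance: float
    mean_distance: float


def summarize_loci(links: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Summarize links per locus and in total.

    Returns a per-locus frame (locus_id, cv_count, n_target_genes,
    target_genes, median/mean distance) and grand totals: distinct CVs and
    distinct genes over all loci, plus per-source median/mean link distances.
    """
    if len(links) == 0:
        totals = {
            "total_cvs": 0,
            "total_genes": 0,
            "per_source_median_distance": {},
            "per_source_mean_distance": {},
        }
        cols = ["locus_id", "cv_count", "n_target_genes", "target_genes",
                "median_distance", "mean_distance"]
        return pd.DataFrame(columns=cols), totals
    rows = []
    for locus, grp in links.groupby("locus_id", sort=True):
        genes = tuple(sorted(grp["gene_id"].unique()))
        rows.append(
            {
                "locus_id": locus,
                "cv_count": grp["variant_id"].nunique(),
                "n_target_genes": len(genes),
                "target_genes": ",".join(genes),
                "median_distance": float(grp["distance"].median()),
                "mean_distance": float(grp["distance"].mean()),
            }
        )
    per_locus = pd.DataFrame(rows)
    per_source_median, per_source_mean = {}, {}
    expanded = links.assign(_src=links["source"].astype(str).str.split(",")).explode("_src")
    for src, grp in expanded.groupby("_src", sort=True):
        if src == "":
            continue
        per_source_median[src] = float(grp["distance"].median())
        per_source_mean[src] = float(grp["distance"].mean())
    totals = {
        "total_cvs": int(links["variant_id"].nunique()),
        "total_genes": int(links["gene_id"].nunique()),
        "per_source_median_distance": per_source_median,
        "per_source_mean_distance": per_source_mean,
    }
    return per_locus, totals


def load_published_locus_table() -> pd.DataFrame:
    """Published per-locus credible-variant counts and HiChIP target genes.

    The table covers the 14 epithelial-ovarian-cancer GWAS risk loci with
    loop-linked credible variants; columns are locus (cytoband), cv_count and
    the comma-separated target gene symbols.
    """
    with resources.files("loopgene.data").joinpath("eoc_risk_loci.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
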