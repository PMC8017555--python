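"""File formats: summary stats, valid pairs, contact matrices, GTF, BED,
BEDPE loops, WashU longrange tracks, link tables, truth records.

Conventions: BED/BEDPE and all internal coordinates are half-open 0-based;
GTF and allValidPairs positions are 1-based (inclusive for GTF) at the text
boundary only.  Every writer/reader pair round-trips losslessly.  Writers
accept an optional provenance block (emitted as leading '#' comment lines);
readers skip comment lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges
import yaml

from . import __version__
from .annotation import GeneModel
from .config import ConfigurationError
from .synthetic import Study, TruthRecord

__all__ = [
    "FormatError",
    "PipelineConfig",
    "provenance_lines",
    "read_summary_stats", "write_summary_stats",
    "read_valid_pairs", "write_valid_pairs",
    "read_bins_matrix", "write_bins_matrix",
    "read_gtf", "write_gtf",
    "read_bed", "write_bed",
    "read_loops_bedpe", "write_loops_bedpe",
    "read_longrange", "write_longrange",
    "read_links", "write_links",
    "read_credible_sets", "write_credible_sets",
    "read_truth", "write_truth",
    "read_expression", "write_expression",
    "read_gene_list", "write_gene_list",
    "write_study",
]


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# provenance

def provenance_lines(seed=None, config=None) -> list[str]:
    """Provenance comment block: package version, seed, config hash."""
    lines = [f"# loopgene_version={__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        digest = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
        lines.append(f"# config_hash={digest}")
    return lines


def _write_table(df: pd.DataFrame, path, header=True, provenance=None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in provenance or []:
            fh.write(line.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False, header=header)


# ---------------------------------------------------------------------------
# GWAS summary statistics

SUMSTATS_COLUMNS = ["variant_id", "chrom", "pos", "beta", "se", "locus_id"]


def write_summary_stats(df: pd.DataFrame, path, provenance=None) -> None:
    _write_table(df[SUMSTATS_COLUMNS], path, provenance=provenance)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    missing = set(SUMSTATS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if (df["se"] <= 0).any():
        bad = int(df.index[df["se"] <= 0][0]) + 2  # 1-based incl. header
        raise FormatError(f"{path}: non-positive se at line {bad}")
    return df[SUMSTATS_COLUMNS + [c for c in df.columns if c not in SUMSTATS_COLUMNS]]


# ---------------------------------------------------------------------------
# allValidPairs

VALIDPAIR_COLUMNS = ["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


def write_valid_pairs(df: pd.DataFrame, path) -> None:
    df[VALIDPAIR_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_valid_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 7:
        raise FormatError(f"{path}: expected >= 7 tab-separated columns")
    df = df.iloc[:, :7]
    df.columns = VALIDPAIR_COLUMNS
    for col in ("pos1", "pos2"):
        if (df[col] < 1).any():
            line = int(df.index[df[col] < 1][0]) + 1
            raise FormatError(f"{path}: position < 1 at line {line}")
    return df


# ---------------------------------------------------------------------------
# HiC-Pro-style bins BED + triplet matrix


def write_bins_matrix(
    binpairs: pd.DataFrame,
    chrom_sizes: dict[str, int],
    resolution: int,
    bins_path,
    matrix_path,
) -> None:
    """Write a bins BED (chrom, start, end, 1-based id) and sparse triplets."""
    rows = []
    idx = 1
    index_of: dict[tuple[str, int], int] = {}
    for chrom in sorted(chrom_sizes):
        n_bins = chrom_sizes[chrom] // resolution
        for b in range(n_bins):
            rows.append((chrom, b * resolution, min((b + 1) * resolution, chrom_sizes[chrom]), idx))
            index_of[(chrom, b)] = idx
            idx += 1
    pd.DataFrame(rows).to_csv(bins_path, sep="\t", index=False, header=False)
    trip = pd.DataFrame(
        {
            "i": [index_of[(r.chrom, r.bin1)] for r in binpairs.itertuples()],
            "j": [index_of[(r.chrom, r.bin2)] for r in binpairs.itertuples()],
            "count": binpairs["count"].to_numpy(),
        }
    )
    trip.to_csv(matrix_path, sep="\t", index=False, header=False)


def read_bins_matrix(bins_path, matrix_path) -> tuple[pd.DataFrame, dict[str, int], int]:
    """Read bins + triplets back into (binpairs, chrom_sizes, resolution)."""
    bins = pd.read_csv(bins_path, sep="\t", header=None, names=["chrom", "start", "end", "id"], comment="#")
    if (bins["start"] >= bins["end"]).any():
        line = int(bins.index[bins["start"] >= bins["end"]][0]) + 1
        raise FormatError(f"{bins_path}: start >= end at line {line}")
    widths = (bins["end"] - bins["start"]).to_numpy()
    resolution = int(np.bincount(widths).argmax()) if len(widths) else 0
    chrom_sizes = bins.groupby("chrom")["end"].max().to_dict()
    lookup = {int(r.id): (r.chrom, int(r.start) // resolution) for r in bins.itertuples()}
    trip = pd.read_csv(matrix_path, sep="\t", header=None, names=["i", "j", "count"], comment="#")
    if (trip["count"] < 0).any() or not np.issubdtype(trip["count"].dtype, np.integer):
        raise FormatError(f"{matrix_path}: counts must be non-negative integers")
    records = []
    for r in trip.itertuples():
        if r.i not in lookup or r.j not in lookup:
            raise FormatError(f"{matrix_path}: bin id out of range at line {r.Index + 1}")
        c1, b1 = lookup[r.i]
        c2, b2 = lookup[r.j]
        if c1 != c2:
            continue  # trans entries are out of scope
        records.append((c1, min(b1, b2), max(b1, b2), int(r.count)))
    binpairs = pd.DataFrame(records, columns=["chrom", "bin1", "bin2", "count"])
    return binpairs, {k: int(v) for k, v in chrom_sizes.items()}, resolution


# ---------------------------------------------------------------------------
# GTF


def write_gtf(genes: list[GeneModel], path, source: str = "loopgene") -> None:
    """Write gene models as GTF (1-based inclusive) with gene/exon/UTR rows."""
    with Path(path).open("w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'

            def _row(feature: str, s: int, e: int) -> str:
                return (
                    f"{g.chrom}\t{source}\t{feature}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )

            fh.write(_row("gene", g.start, g.end))
            for s, e in g.exons:
                fh.write(_row("exon", s, e))
            for s, e in g.five_utr:
                fh.write(_row("five_prime_utr", s, e))
            for s, e in g.three_utr:
                fh.write(_row("three_prime_utr", s, e))


def read_gtf(path) -> list[GeneModel]:
    """Read gene models from GTF (gene/exon/UTR features; gene_id, gene_name)."""
    df = pyranges.read_gtf(str(path)).df
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: GTF lacks gene_id attributes")
    genes = []
    for gid, grp in df.groupby("gene_id", sort=True):
        grow = grp[grp["Feature"] == "gene"]
        if len(grow) != 1:
            raise FormatError(f"{path}: gene {gid} must have exactly one gene row")
        grow = grow.iloc[0]
        exons = tuple(
            sorted((int(r.Start), int(r.End)) for r in grp[grp["Feature"] == "exon"].itertuples())
        )
        five = tuple(
            sorted(
                (int(r.Start), int(r.End))
                for r in grp[grp["Feature"] == "five_prime_utr"].itertuples()
            )
        )
        three = tuple(
            sorted(
                (int(r.Start), int(r.End))
                for r in grp[grp["Feature"] == "three_prime_utr"].itertuples()
            )
        )
        symbol = grow.get("gene_name", gid) if hasattr(grow, "get") else gid
        genes.append(
            GeneModel(
                gene_id=str(gid),
                symbol=str(symbol),
                chrom=str(grow["Chromosome"]),
                strand=str(grow["Strand"]),
                start=int(grow["Start"]),
                end=int(grow["End"]),
                exons=exons if exons else ((int(grow["Start"]), int(grow["End"])),),
                five_utr=five,
                three_utr=three,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# BED


def write_bed(df: pd.DataFrame, path, provenance=None) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in df.columns]
    _write_table(df[cols], path, header=False, provenance=provenance)


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = names[: df.shape[1]]
    bad = df["start"] >= df["end"]
    if bad.any():
        raise FormatError(f"{path}: start >= end at line {int(df.index[bad][0]) + 1}")
    if (df["start"] < 0).any():
        raise FormatError(f"{path}: negative coordinate")
    return df


# ---------------------------------------------------------------------------
# loops: BEDPE and WashU longrange

LOOP_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "count", "expected", "p_value", "q_value", "distance", "source",
]


def write_loops_bedpe(loops: pd.DataFrame, path, provenance=None) -> None:
    """BEDPE: ten standard columns (q value in score) plus statistic columns."""
    out = pd.DataFrame(
        {
            "chrom1": loops["chrom1"],
            "start1": loops["start1"],
            "end1": loops["end1"],
            "chrom2": loops["chrom2"],
            "start2": loops["start2"],
            "end2": loops["end2"],
            "name": [f"loop{k + 1}" for k in range(len(loops))],
            "score": loops["q_value"],
            "strand1": ".",
            "strand2": ".",
            "count": loops["count"],
            "expected": loops["expected"],
            "p_value": loops["p_value"],
            "distance": loops["distance"],
            "sources": loops["source"],
        }
    )
    _write_table(out, path, header=False, provenance=provenance)


def read_loops_bedpe(path) -> pd.DataFrame:
    names = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
        "strand1", "strand2", "count", "expected", "p_value", "distance", "sources",
    ]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 10:
        raise FormatError(f"{path}: BEDPE needs at least 10 columns")
    df.columns = names[: df.shape[1]]
    for a, b in (("start1", "end1"), ("start2", "end2")):
        bad = df[a] >= df[b]
        if bad.any():
            raise FormatError(f"{path}: {a} >= {b} at line {int(df.index[bad][0]) + 1}")
    out = pd.DataFrame(
        {
            "chrom1": df["chrom1"], "start1": df["start1"], "end1": df["end1"],
            "chrom2": df["chrom2"], "start2": df["start2"], "end2": df["end2"],
            "count": df.get("count"), "expected": df.get("expected"),
            "p_value": df.get("p_value"), "q_value": df["score"],
            "distance": df.get("distance"), "source": df.get("sources"),
        }
    )
    return out


LONGRANGE_QCAP = 300.0  # cap on -log10(q) in track scores


def write_longrange(loops: pd.DataFrame, path) -> None:
    """WashU longrange text: one record per loop direction, score -log10(q)."""
    with Path(path).open("w") as fh:
        for r in loops.itertuples():
            q = max(float(r.q_value), 10.0 ** (-LONGRANGE_QCAP))
            score = min(-np.log10(q), LONGRANGE_QCAP)
            fh.write(
                f"{r.chrom1}\t{r.start1}\t{r.end1}\t{r.chrom2}:{r.start2}-{r.end2},{score:g}\n"
            )
            fh.write(
                f"{r.chrom2}\t{r.start2}\t{r.end2}\t{r.chrom1}:{r.start1}-{r.end1},{score:g}\n"
            )


def read_longrange(path) -> pd.DataFrame:
    rows = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                chrom, start, end, target = line.rstrip("\n").split("\t")
                rest, score = target.rsplit(",", 1)
                chrom2, span = rest.split(":")
                s2, e2 = span.split("-")
                rows.append(
                    (chrom, int(start), int(end), chrom2, int(s2), int(e2), float(score))
                )
            except ValueError as exc:
                raise FormatError(f"{path}: malformed longrange record at line {lineno}") from exc
    return pd.DataFrame(
        rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "score"]
    )


# ---------------------------------------------------------------------------
# link tables, credible sets, truth, expression, gene lists


def write_links(links: pd.DataFrame, path, provenance=None) -> None:
    _write_table(links, path, provenance=provenance)


def read_links(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_credible_sets(credible_sets: dict, path, provenance=None) -> None:
    """Per-locus variant table: abf, pp, membership flag, credible level."""
    frames = []
    for locus in sorted(credible_sets):
        cs = credible_sets[locus]
        t = cs.table.copy()
        t["level"] = cs.level
        frames.append(t)
    _write_table(pd.concat(frames, ignore_index=True), path, provenance=provenance)


def read_credible_sets(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"variant_id", "locus_id", "pp", "in_credible_set"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_truth(truth: TruthRecord, path, provenance=None) -> None:
    payload = truth.to_dict()
    if provenance:
        payload["_provenance"] = [l.lstrip("# ") for l in provenance]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth(path) -> TruthRecord:
    return TruthRecord.from_dict(json.loads(Path(path).read_text()))


def write_expression(expression: pd.DataFrame, labels: pd.Series, expr_path, labels_path) -> None:
    expression.to_csv(expr_path, sep="\t", index_label="gene_id")
    labels.rename("group").to_frame().to_csv(labels_path, sep="\t", index_label="sample")


def read_expression(expr_path, labels_path) -> tuple[pd.DataFrame, pd.Series]:
    expr = pd.read_csv(expr_path, sep="\t", index_col="gene_id", comment="#")
    labels = pd.read_csv(labels_path, sep="\t", index_col="sample", comment="#")["group"]
    extra = set(expr.columns) - set(labels.index)
    if extra:
        raise FormatError(f"{labels_path}: samples without labels: {sorted(extra)}")
    return expr, labels


def write_gene_list(genes, path) -> None:
    pd.Series(sorted(set(map(str, genes)))).to_csv(path, sep="\t", index=False, header=False)


def read_gene_list(path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return sorted(set(df.iloc[:, 0].astype(str)))


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run parameters, loadable from a flat YAML mapping."""

    resolution: int = 5_000
    d_min: int = 20_000
    d_max: int = 2_000_000
    fdr: float = 0.01
    level: float = 0.99
    prior_var: float = 0.04
    promoter_upstream: int = 2_500
    promoter_downstream: int = 2_500
    peak_filter_require_all: bool = True
    gene_mode: str = "promoter"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigurationError("resolution must be positive")
        if not (0 <= self.d_min <= self.d_max):
            raise ConfigurationError("need 0 <= d_min <= d_max")
        if not (0.0 < self.fdr <= 1.0):
            raise ConfigurationError("fdr must lie in (0, 1]")
        if not (0.0 < self.level <= 1.0):
            raise ConfigurationError("level must lie in (0, 1]")
        if self.prior_var < 0:
            raise ConfigurationError("prior_var must be >= 0")
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ConfigurationError("promoter windows must be >= 0")
        if self.gene_mode not in ("promoter", "body"):
            raise ConfigurationError("gene_mode must be 'promoter' or 'body'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# whole-study writer


def write_study(study: Study, outdir) -> dict[str, Path]:
    """Write every input file of a synthetic study into a directory.

    Returns the mapping of logical names to paths.  File formats match what
    the corresponding readers (and the CLI stages) consume.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = provenance_lines(seed=study.config.seed, config=study.config)
    paths: dict[str, Path] = {}

    paths["sumstats"] = outdir / "sumstats.tsv"
    write_summary_stats(study.sumstats, paths["sumstats"], provenance=prov)

    paths["valid_pairs"] = outdir / "sample.allValidPairs"
    write_valid_pairs(study.valid_pairs, paths["valid_pairs"])

    for cl, bp in study.binpairs.items():
        bins = outdir / f"{cl}_bins.bed"
        mat = outdir / f"{cl}_matrix.tsv"
        write_bins_matrix(bp, study.chrom_sizes, study.config.bin_resolution, bins, mat)
        paths[f"bins_{cl}"] = bins
        paths[f"matrix_{cl}"] = mat

    paths["gtf"] = outdir / "genes.gtf"
    write_gtf(study.genes, paths["gtf"])

    for cl, peaks in study.peaks.items():
        p = outdir / f"peaks_{cl}.bed"
        write_bed(peaks, p)
        paths[f"peaks_{cl}"] = p

    paths["expression"] = outdir / "expression.tsv"
    paths["labels"] = outdir / "labels.tsv"
    write_expression(study.expression, study.labels, paths["expression"], paths["labels"])

    paths["eqtl_genes"] = outdir / "eqtl_targets.tsv"
    write_gene_list(study.eqtl_genes, paths["eqtl_genes"])

    paths["truth"] = outdir / "truth.json"
    write_truth(study.truth, paths["truth"], provenance=prov)

    with (outdir / "sim_config.yaml").open("w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(study.config).items()},
            fh,
        )
    paths["sim_config"] = outdir / "sim_config.yaml"
    return paths
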