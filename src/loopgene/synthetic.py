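"""Synthetic study generator.

Produces every input the variant-to-gene pipeline consumes, with the
statistical structure the downstream analysis assumes:

* an LD-structured founder haplotype panel (first-order Markov copying on the
  allele-frequency quantile scale) with one planted causal variant per locus
  and marginal OLS summary statistics for a standardized quantitative trait;
* 5 kb-binned cis contact counts with power-law distance decay, multiplicative
  log-normal per-bin visibility bias, Poisson (optionally gamma-Poisson)
  counting noise, and planted loops at log-uniform anchor separations;
* HiC-Pro-style valid-pair records with a requested duplicate / trans /
  cis-short composition;
* a packed, non-overlapping gene annotation with exon structure; and
* a log2-scale tumor/normal expression matrix with planted differential genes.

Every generator is a pure function of (config, seed); a :class:`TruthRecord`
lists each planted object exactly once for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .config import ConfigurationError, SimConfig

__all__ = [
    "GenotypePanel",
    "TruthRecord",
    "Study",
    "effect_for_z",
    "sim_panel",
    "sim_gwas_locus",
    "sim_contacts",
    "plant_loops",
    "sim_valid_pairs",
    "sim_genome_annotation",
    "sim_expression",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypePanel:
    """Dosage matrix for one locus plus the variant metadata it carries."""

    locus_id: str
    chrom: str
    variant_ids: list[str]
    positions: np.ndarray  # 1-based bp, ascending
    dosages: np.ndarray  # n_individuals x m, values {0,1,2}
    founder_freqs: np.ndarray  # target allele frequencies of the founder pool
    maf: np.ndarray  # realized minor-allele frequency of the dosage matrix
    haplotypes: np.ndarray | None = None  # founder pool (n_haplotypes x m)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class TruthRecord:
    """Planted objects of one synthetic study, each listed exactly once."""

    causal_variant_per_locus: dict[str, str] = field(default_factory=dict)
    planted_loop_coords: list[dict] = field(default_factory=list)
    de_gene_ids: list[str] = field(default_factory=list)
    planted_links: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "causal_variant_per_locus": self.causal_variant_per_locus,
            "planted_loop_coords": self.planted_loop_coords,
            "de_gene_ids": self.de_gene_ids,
            "planted_links": self.planted_links,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthRecord":
        return cls(
            causal_variant_per_locus=dict(d["causal_variant_per_locus"]),
            planted_loop_coords=list(d["planted_loop_coords"]),
            de_gene_ids=list(d["de_gene_ids"]),
            planted_links=list(d["planted_links"]),
        )


@dataclass
class Study:
    """All inputs of one end-to-end synthetic study, in memory."""

    config: SimConfig
    chrom_sizes: dict[str, int]
    panels: dict[str, GenotypePanel]
    sumstats: pd.DataFrame
    genes: list[GeneModel]
    binpairs: dict[str, pd.DataFrame]  # cell line -> binned contact counts
    valid_pairs: pd.DataFrame
    peaks: dict[str, pd.DataFrame]  # cell line -> open-chromatin intervals
    expression: pd.DataFrame
    labels: pd.Series
    eqtl_genes: list[str]
    truth: TruthRecord


# ---------------------------------------------------------------------------
# genotypes and GWAS summary statistics


def effect_for_z(z: float, n: int, maf: float) -> float:
    """Per-allele effect giving expected marginal z-score ``z`` at sample size ``n``.

    Under Hardy-Weinberg the causal dosage variance is 2*maf*(1-maf), so the
    expected z of the causal variant is effect * sqrt(n * 2*maf*(1-maf)).
    """
    return float(z) / np.sqrt(n * 2.0 * maf * (1.0 - maf))


def _sim_founders(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Founder haplotypes by first-order Markov copying.

    A latent uniform quantile per SNP persists to the next SNP with
    probability ``adjacent_corr`` and is redrawn otherwise; the allele is the
    indicator that the quantile falls below the SNP's allele frequency.
    Frequencies are sorted along the locus so neighboring SNPs have nearly
    equal marginals and the indicator correlation tracks the copying rate.

    With ``corr_block_range`` set, the copying rate varies in haplotype-like
    blocks (geometric lengths around ``corr_block_len`` SNPs, rate uniform in
    the range), producing the heterogeneous LD-score landscape real panels
    show; ``adjacent_corr`` then only sets the scale of the first SNP.
    """
    m = config.n_snps_per_locus
    h = config.n_haplotypes
    lo, hi = config.maf_range
    freqs = np.sort(rng.uniform(lo, hi, size=m))
    if config.corr_block_range is None:
        copy_rate = np.full(m, config.adjacent_corr)
    else:
        clo, chi = config.corr_block_range
        copy_rate = np.empty(m)
        j = 0
        while j < m:
            span = 1 + rng.geometric(1.0 / config.corr_block_len)
            copy_rate[j : j + span] = rng.uniform(clo, chi)
            j += span
    u = np.empty((h, m))
    u[:, 0] = rng.random(h)
    for j in range(1, m):
        fresh = rng.random(h)
        keep = rng.random(h) < copy_rate[j]
        u[:, j] = np.where(keep, u[:, j - 1], fresh)
    haplotypes = (u < freqs[None, :]).astype(np.int8)
    # guard against monomorphic columns in tiny pools
    for j in np.flatnonzero(haplotypes.sum(axis=0) % h == 0):
        flip = rng.integers(h)
        haplotypes[flip, j] = 1 - haplotypes[flip, j]
    return haplotypes, freqs


def sim_panel(
    config: SimConfig,
    chrom: str = "chrS1",
    locus_id: str = "locus1",
    seed: int | np.random.SeedSequence | None = None,
) -> GenotypePanel:
    """Simulate an LD-structured genotype panel for one locus.

    Individuals draw two founder haplotypes with replacement, so dosages are
    Hardy-Weinberg at the realized founder frequencies and carry the founders'
    first-order LD.  SNP positions are evenly spaced along the chromosome.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    haplotypes, freqs = _sim_founders(config, rng)
    n = config.n_individuals
    i1 = rng.integers(config.n_haplotypes, size=n)
    i2 = rng.integers(config.n_haplotypes, size=n)
    dosages = (haplotypes[i1] + haplotypes[i2]).astype(np.int8)
    m = config.n_snps_per_locus
    positions = np.floor((np.arange(m) + 0.5) * config.chrom_length / m).astype(np.int64) + 1
    variant_ids = [f"{locus_id}_snp{j + 1:04d}" for j in range(m)]
    afreq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(afreq, 1.0 - afreq)
    return GenotypePanel(
        locus_id=locus_id,
        chrom=chrom,
        variant_ids=variant_ids,
        positions=positions,
        dosages=dosages,
        founder_freqs=freqs,
        maf=maf,
        haplotypes=haplotypes,
    )


def sim_gwas_locus(
    panel: GenotypePanel,
    causal_variant: str | int,
    effect: float,
    n_individuals: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Marginal OLS association statistics for one locus with one causal variant.

    The phenotype is ``y = effect * g_causal + noise`` with total variance 1;
    each SNP is regressed on y separately and its slope and standard error
    reported, as in a standard quantitative-trait GWAS.

    Returns a frame with columns variant_id, chrom, pos, beta, se, locus_id.
    """
    rng = np.random.default_rng(seed)
    n = panel.n_individuals if n_individuals is None else int(n_individuals)
    if n < 10:
        raise ValueError(f"need at least 10 individuals, got {n}")
    if n > panel.n_individuals:
        raise ValueError("n_individuals exceeds panel size")
    if isinstance(causal_variant, str):
        try:
            c = panel.variant_ids.index(causal_variant)
        except ValueError:
            raise ValueError(f"{causal_variant!r} is not a variant of this panel") from None
    else:
        c = int(causal_variant)
        if not 0 <= c < panel.n_snps:
            raise ValueError("causal variant index out of range")

    X = panel.dosages[:n].astype(np.float64)
    g = X[:, c]
    var_g = g.var()
    noise_var = max(1.0 - effect * effect * var_g, 1e-12)
    y = effect * g + rng.normal(0.0, np.sqrt(noise_var), size=n)

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (Xc * Xc).sum(axis=0)
    sxy = Xc.T @ yc
    syy = float(yc @ yc)
    beta = sxy / sxx
    rss = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx)
    return pd.DataFrame(
        {
            "variant_id": panel.variant_ids,
            "chrom": panel.chrom,
            "pos": panel.positions,
            "beta": beta,
            "se": se,
            "locus_id": panel.locus_id,
        }
    )


# ---------------------------------------------------------------------------
# contact maps


def plant_loops(
    config: SimConfig,
    rng: np.random.Generator,
    n_bins: int,
    n_loops: int | None = None,
    required: list[tuple[int, int]] | None = None,
) -> list[tuple[int, int]]:
    """Draw planted loop bin pairs with log-uniform anchor separations.

    ``required`` pairs (e.g. a causal-variant bin paired with a gene-promoter
    bin) are kept as-is; the remainder are placed uniformly along the
    chromosome.  All pairs are validated against the chromosome extent and the
    [20 kb, 2 Mb] distance filter.
    """
    res = config.bin_resolution
    glo, ghi = config.loop_gap_range
    gap_lo = max(1, int(np.ceil(glo / res)))
    gap_hi = min(n_bins - 1, int(ghi // res))
    if gap_hi < gap_lo:
        raise ConfigurationError("chromosome too short for the requested loop gaps")
    n_total = config.n_planted_loops if n_loops is None else n_loops
    planted: list[tuple[int, int]] = []
    seen = set()
    for pair in required or []:
        i, j = int(min(pair)), int(max(pair))
        _validate_planted(i, j, n_bins, res)
        if (i, j) not in seen:
            planted.append((i, j))
            seen.add((i, j))
    tries = 0
    while len(planted) < n_total:
        tries += 1
        if tries > 1000 * max(n_total, 1):
            raise ConfigurationError("could not place the requested planted loops")
        gap = int(round(np.exp(rng.uniform(np.log(gap_lo), np.log(gap_hi)))))
        gap = min(max(gap, gap_lo), gap_hi)
        i = int(rng.integers(0, n_bins - gap))
        j = i + gap
        if (i, j) not in seen:
            planted.append((i, j))
            seen.add((i, j))
    return planted


def _validate_planted(i: int, j: int, n_bins: int, res: int) -> None:
    if not (0 <= i < j < n_bins):
        raise ValueError(f"planted bin pair ({i},{j}) beyond chromosome end")
    d = (j - i) * res
    if not (20_000 <= d <= 2_000_000):
        raise ValueError(f"planted loop separation {d} bp outside [20 kb, 2 Mb]")


def sim_contacts(
    config: SimConfig,
    chrom: str = "chrS1",
    seed: int | np.random.SeedSequence | None = None,
    planted: list[tuple[int, int]] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Simulate 5 kb-binned cis contact counts for one chromosome.

    The expected count of bin pair (i, j) is
    ``depth * p(d_ij) * b_i * b_j`` with ``p(d) ~ d**(-decay_exponent)``
    normalized over all modeled pairs and ``b`` the per-bin bias (log-normal,
    mean 1).  Planted pairs have their mean multiplied by ``loop_fold``.
    Counts are Poisson, or gamma-Poisson when ``overdispersion > 0``.

    Returns the sparse nonzero counts (chrom, bin1, bin2, count) and a record
    of the planted loops.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    res = config.bin_resolution
    n_bins = config.chrom_length // res
    if n_bins < 2:
        raise ConfigurationError("chromosome shorter than two bins")

    bias = np.exp(rng.normal(0.0, config.bias_sd, size=n_bins))
    bias /= bias.mean()

    if planted is None:
        planted = plant_loops(config, rng, n_bins) if config.n_planted_loops else []
    for i, j in planted:
        _validate_planted(i, j, n_bins, res)

    max_gap = min(n_bins - 1, 2_000_000 // res)
    ii = np.concatenate([np.arange(n_bins - g) for g in range(1, max_gap + 1)])
    jj = np.concatenate([np.arange(n_bins - g) + g for g in range(1, max_gap + 1)])
    d = (jj - ii).astype(np.float64) * res
    w = d ** (-config.decay_exponent)
    w /= w.sum()
    mean = config.sequencing_depth * w * bias[ii] * bias[jj]
    if planted:
        idx = {(i, j): None for i, j in planted}
        mask = np.fromiter(((a, b) in idx for a, b in zip(ii, jj)), bool, len(ii))
        mean[mask] *= config.loop_fold
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        mean = rng.gamma(shape, mean / shape)
    counts = rng.poisson(mean)

    keep = counts > 0
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "bin1": ii[keep].astype(np.int64),
            "bin2": jj[keep].astype(np.int64),
            "count": counts[keep].astype(np.int64),
        }
    )
    coords = [
        {
            "chrom": chrom,
            "bin1": int(i),
            "bin2": int(j),
            "start1": int(i * res),
            "end1": int((i + 1) * res),
            "start2": int(j * res),
            "end2": int((j + 1) * res),
            "distance": int((j - i) * res),
        }
        for i, j in planted
    ]
    return df, coords


# ---------------------------------------------------------------------------
# valid pairs


def sim_valid_pairs(
    config: SimConfig,
    n_pairs: int = 10_000,
    chrom: str = "chrS1",
    trans_chrom: str = "chrS2",
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Simulate HiC-Pro-style valid-pair records with a requested composition.

    Category counts (duplicate / trans / cis-short / cis-long) are a single
    multinomial draw over all records; duplicates are byte-identical
    coordinate copies of previously emitted unique records under fresh read
    ids.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    p_dup = config.dup_fraction
    p_trans = config.trans_fraction
    p_short = config.cis_short_fraction
    p_long = 1.0 - p_dup - p_trans - p_short
    n_dup, n_trans, n_short, n_long = rng.multinomial(
        n_pairs, [p_dup, p_trans, p_short, max(p_long, 0.0)]
    )
    n_unique = n_trans + n_short + n_long
    if n_dup > 0 and n_unique == 0:
        raise ConfigurationError("cannot emit duplicates without any unique pairs")

    L = config.chrom_length
    strands = np.array(["+", "-"])

    def _cis(n: int, gap_lo: int, gap_hi: int) -> pd.DataFrame:
        gap_hi = min(gap_hi, L - 2)
        gap_lo = min(gap_lo, gap_hi)
        gap = rng.integers(gap_lo, gap_hi + 1, size=n)
        pos1 = 1 + np.floor(rng.random(n) * (L - gap)).astype(np.int64)
        return pd.DataFrame(
            {
                "chrom1": chrom,
                "pos1": pos1,
                "strand1": rng.choice(strands, n),
                "chrom2": chrom,
                "pos2": pos1 + gap,
                "strand2": rng.choice(strands, n),
            }
        )

    frames = []
    if n_long:
        frames.append(_cis(n_long, 20_001, min(1_500_000, L - 1)))
    if n_short:
        frames.append(_cis(n_short, 100, 20_000))
    if n_trans:
        frames.append(
            pd.DataFrame(
                {
                    "chrom1": chrom,
                    "pos1": rng.integers(1, L, size=n_trans),
                    "strand1": rng.choice(strands, n_trans),
                    "chrom2": trans_chrom,
                    "pos2": rng.integers(1, L, size=n_trans),
                    "strand2": rng.choice(strands, n_trans),
                }
            )
        )
    unique = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    )
    if n_dup:
        dup = unique.iloc[rng.integers(0, len(unique), size=n_dup)].reset_index(drop=True)
        out = pd.concat([unique, dup], ignore_index=True)
    else:
        out = unique
    out = out.iloc[rng.permutation(len(out))].reset_index(drop=True)
    out.insert(0, "read_id", [f"read{k + 1:07d}" for k in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# gene annotation


def sim_genome_annotation(
    config: SimConfig,
    chrom: str = "chrS1",
    seed: int | np.random.SeedSequence | None = None,
) -> list[GeneModel]:
    """Place non-overlapping gene models with exon structure on one chromosome.

    Gene spans are uniform in ``gene_span_range``; gaps between genes come
    from a uniform random partition of the remaining free space.  Each gene gets 1-4
    exons whose first/last intervals carry short UTR annotations when wide
    enough.  Raises when the genes cannot be packed into the chromosome.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_genes
    lo, hi = config.gene_span_range
    spans = rng.integers(lo, hi + 1, size=n)
    free = config.chrom_length - int(spans.sum())
    if free < n + 1:
        raise ConfigurationError(
            f"cannot pack {n} genes of total span {int(spans.sum())} "
            f"into {config.chrom_length} bp"
        )
    cuts = np.sort(rng.choice(free, size=n, replace=False))
    starts = cuts + np.concatenate([[0], np.cumsum(spans[:-1])])
    genes = []
    for k in range(n):
        start, end = int(starts[k]), int(starts[k] + spans[k])
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 5))
        if n_ex == 1:
            exons = [(start, end)]
        else:
            inner = np.sort(rng.choice(np.arange(start + 1, end - 1), size=2 * (n_ex - 1), replace=False))
            bounds = [start, *inner.tolist(), end]
            exons = [(bounds[2 * t], bounds[2 * t + 1]) for t in range(n_ex)]
        five_exon = exons[0] if strand == "+" else exons[-1]
        three_exon = exons[-1] if strand == "+" else exons[0]
        five_utr: tuple = ()
        three_utr: tuple = ()
        if five_exon[1] - five_exon[0] > 400:
            five_utr = (
                ((five_exon[0], five_exon[0] + 150),)
                if strand == "+"
                else ((five_exon[1] - 150, five_exon[1]),)
            )
        if three_exon[1] - three_exon[0] > 400 and three_exon != five_exon:
            three_utr = (
                ((three_exon[1] - 150, three_exon[1]),)
                if strand == "+"
                else ((three_exon[0], three_exon[0] + 150),)
            )
        gid = f"{chrom}_g{k + 1:03d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=gid.upper(),
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                exons=tuple(exons),
                five_utr=five_utr,
                three_utr=three_utr,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# expression


def sim_expression(
    genes: list[GeneModel],
    config: SimConfig,
    seed: int | np.random.SeedSequence | None = None,
    de_genes: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Log2-scale expression matrix with planted tumor-shifted genes.

    Baseline log2 intensities are normal per gene (i.e. raw intensities are
    log-normal); ``de_genes`` (or a random ``de_fraction`` of genes) are
    shifted by ``de_lfc`` in the tumor group.  Returns (matrix, labels,
    planted gene ids); columns are tumor samples first.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.n_tumor < 2 or config.n_normal < 2:
        raise ConfigurationError("need at least 2 tumor and 2 normal samples")
    gene_ids = [g.gene_id for g in genes]
    n_g = len(gene_ids)
    n_s = config.n_tumor + config.n_normal
    mu = rng.normal(7.0, 1.5, size=n_g)
    mat = mu[:, None] + rng.normal(0.0, 1.0, size=(n_g, n_s))
    if de_genes is None:
        n_de = int(round(config.de_fraction * n_g))
        de_genes = sorted(rng.choice(gene_ids, size=n_de, replace=False).tolist())
    else:
        missing = set(de_genes) - set(gene_ids)
        if missing:
            raise ValueError(f"de_genes not in annotation: {sorted(missing)}")
        de_genes = sorted(set(de_genes))
    de_idx = [gene_ids.index(g) for g in de_genes]
    mat[np.array(de_idx, dtype=int)[:, None], : config.n_tumor] += config.de_lfc if de_idx else 0
    cols = [f"T{k + 1:02d}" for k in range(config.n_tumor)] + [
        f"N{k + 1:02d}" for k in range(config.n_normal)
    ]
    df = pd.DataFrame(mat, index=gene_ids, columns=cols)
    labels = pd.Series(
        ["tumor"] * config.n_tumor + ["normal"] * config.n_normal, index=cols, name="group"
    )
    return df, labels, list(de_genes)


# ---------------------------------------------------------------------------
# heritability-enrichment GWAS (for the stratified LD-score regression)


def sim_heritability_gwas(
    panel: GenotypePanel,
    category_mask: np.ndarray,
    h2: float = 0.5,
    enrichment: float = 5.0,
    seed: int | np.random.SeedSequence | None = None,
) -> np.ndarray:
    """Per-SNP GWAS chi-square statistics with a heritability-enriched category.

    Standardized per-SNP effects are drawn so the masked category carries an
    ``enrichment``-fold share of the total heritability ``h2`` relative to its
    SNP share: with category fraction f, the category holds ``enrichment * f``
    of h2 (clamped below 1).

    Marginal z-scores follow the summary-statistic model
    ``z ~ N(sqrt(n) R beta, R)`` with R the LD of the panel's founder pool,
    so E[chi2_j] = 1 + n sum_k R2_jk sigma2_k exactly (the regression
    intercept is 1 by construction).  Sampling uses the founder haplotype
    matrix as a square root of R, avoiding an m x m factorization.
    """
    rng = np.random.default_rng(seed)
    mask = np.asarray(category_mask, dtype=bool)
    if panel.haplotypes is None:
        raise ValueError("panel must carry founder haplotypes")
    n = panel.n_individuals
    m = panel.n_snps
    if mask.shape != (m,):
        raise ValueError("category mask must have one entry per SNP")
    A = getattr(panel, "_ld_operator", None)
    if A is None:
        H = panel.haplotypes.astype(np.float32)
        sd = H.std(axis=0)
        sd[sd == 0] = 1.0
        A = (H - H.mean(axis=0)) / sd / np.sqrt(H.shape[0])  # R = A.T @ A
        panel._ld_operator = A  # cached; founders are immutable after simulation
    f = mask.mean()
    share = min(enrichment * f, 0.99) if mask.any() else 0.0
    var = np.empty(m)
    if mask.any():
        var[mask] = share * h2 / mask.sum()
    var[~mask] = (1.0 - share) * h2 / (~mask).sum()
    beta = rng.normal(0.0, np.sqrt(var))
    eta = rng.normal(size=A.shape[0])
    z = A.T @ (np.sqrt(n) * (A @ beta) + eta)
    return z**2


# ---------------------------------------------------------------------------
# end-to-end study


CELL_LINES = ("CL1", "CL2")


def simulate_study(config: SimConfig, cell_lines: tuple[str, ...] = CELL_LINES) -> Study:
    """Generate a full synthetic study: one chromosome per GWAS locus.

    Per locus the generator plants one causal variant whose bin is looped to a
    gene-promoter bin (the intended variant->gene link), plus background
    loops; contact maps are drawn independently per cell line around the same
    planted loops.  Open-chromatin peak sets cover every causal variant in
    both cell lines.  Differential expression is planted on the linked target
    genes (topped up to ``de_fraction`` with random genes).
    """
    root = np.random.SeedSequence(config.seed)
    truth = TruthRecord()
    chrom_sizes: dict[str, int] = {}
    panels: dict[str, GenotypePanel] = {}
    sumstats_frames: list[pd.DataFrame] = []
    genes: list[GeneModel] = []
    binpairs: dict[str, list[pd.DataFrame]] = {cl: [] for cl in cell_lines}
    peak_rows: dict[str, list[tuple]] = {cl: [] for cl in cell_lines}
    target_genes: list[str] = []
    res = config.bin_resolution
    n_bins = config.chrom_length // res

    for l in range(config.n_loci):
        locus_id = f"locus{l + 1}"
        chrom = f"chrS{l + 1}"
        chrom_sizes[chrom] = config.chrom_length
        (ss_genes, ss_panel, ss_gwas, ss_loops, *ss_contacts) = np.random.SeedSequence(
            entropy=root.entropy, spawn_key=(l,)
        ).spawn(4 + len(cell_lines))

        locus_genes = sim_genome_annotation(config, chrom=chrom, seed=ss_genes)
        genes.extend(locus_genes)
        panel = sim_panel(config, chrom=chrom, locus_id=locus_id, seed=ss_panel)
        panels[locus_id] = panel

        rng_loops = np.random.default_rng(ss_loops)
        causal_idx, gene = _pick_link(panel, locus_genes, config, rng_loops)
        causal_id = panel.variant_ids[causal_idx]
        snp_bin = int((panel.positions[causal_idx] - 1) // res)
        tss_bin = int(gene.tss // res)
        link_pair = (min(snp_bin, tss_bin), max(snp_bin, tss_bin))
        planted = plant_loops(config, rng_loops, n_bins, required=[link_pair])

        effect = (
            config.causal_effect
            if config.causal_effect is not None
            else effect_for_z(config.target_z, panel.n_individuals, float(panel.maf[causal_idx]))
        )
        sumstats_frames.append(sim_gwas_locus(panel, causal_idx, effect, seed=ss_gwas))
        truth.causal_variant_per_locus[locus_id] = causal_id
        truth.planted_links.append(
            {"locus_id": locus_id, "variant_id": causal_id, "gene_id": gene.gene_id}
        )
        target_genes.append(gene.gene_id)

        for cl, ss_cl in zip(cell_lines, ss_contacts):
            df, coords = sim_contacts(config, chrom=chrom, seed=ss_cl, planted=planted)
            binpairs[cl].append(df)
            if cl == cell_lines[0]:
                for c in coords:
                    c["locus_id"] = locus_id
                    c["is_link"] = (c["bin1"], c["bin2"]) == link_pair
                    truth.planted_loop_coords.append(c)

        # open-chromatin peaks: one per causal variant per cell line + background
        for cl in cell_lines:
            pos = int(panel.positions[causal_idx])
            peak_rows[cl].append((chrom, max(pos - 250, 0), pos + 250))
        rng_peaks = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(l, 999))
        )
        for cl in cell_lines:
            for _ in range(20):
                s = int(rng_peaks.integers(0, config.chrom_length - 500))
                peak_rows[cl].append((chrom, s, s + 500))

    ss_expr, ss_vp, ss_eqtl = np.random.SeedSequence(
        entropy=root.entropy, spawn_key=(10_000,)
    ).spawn(3)
    n_de = int(round(config.de_fraction * len(genes)))
    rng_eqtl = np.random.default_rng(ss_eqtl)
    extra = [g.gene_id for g in genes if g.gene_id not in target_genes]
    pad = rng_eqtl.choice(extra, size=max(n_de - len(target_genes), 0), replace=False).tolist()
    de_genes = sorted(set(target_genes) | set(pad))
    expression, labels, de_ids = sim_expression(genes, config, seed=ss_expr, de_genes=de_genes)
    truth.de_gene_ids = de_ids

    # eQTL target list: a subset of true targets plus unrelated genes
    n_true = max(1, len(target_genes) // 2)
    eqtl = sorted(
        set(rng_eqtl.choice(target_genes, size=n_true, replace=False).tolist())
        | set(rng_eqtl.choice(extra, size=min(3, len(extra)), replace=False).tolist())
    )

    valid_pairs = sim_valid_pairs(
        config, n_pairs=10_000, chrom="chrS1",
        trans_chrom="chrS2" if config.n_loci > 1 else "chrS1b", seed=ss_vp,
    )

    return Study(
        config=config,
        chrom_sizes=chrom_sizes,
        panels=panels,
        sumstats=pd.concat(sumstats_frames, ignore_index=True),
        genes=genes,
        binpairs={cl: pd.concat(frames, ignore_index=True) for cl, frames in binpairs.items()},
        valid_pairs=valid_pairs,
        peaks={
            cl: pd.DataFrame(rows, columns=["chrom", "start", "end"])
            .sort_values(["chrom", "start"])
            .reset_index(drop=True)
            for cl, rows in peak_rows.items()
        },
        expression=expression,
        labels=labels,
        eqtl_genes=eqtl,
        truth=truth,
    )


def _pick_link(panel, locus_genes, config, rng):
    """Choose a (causal SNP, target gene) pair loopable at an in-range gap."""
    res = config.bin_resolution
    glo, ghi = config.loop_gap_range
    gap_lo = max(4, int(np.ceil(glo / res)))
    gap_hi = int(ghi // res)
    snp_bins = (panel.positions - 1) // res
    tss_bins = np.array([g.tss // res for g in locus_genes])
    cand = []
    for si, sb in enumerate(snp_bins):
        gaps = np.abs(tss_bins - sb)
        ok = np.flatnonzero((gaps >= gap_lo) & (gaps <= gap_hi))
        cand.extend((si, int(gi)) for gi in ok)
    if not cand:
        raise ConfigurationError(
            "no SNP/gene pair satisfies the planted-loop distance range"
        )
    si, gi = cand[int(rng.integers(len(cand)))]
    return si, locus_genes[gi]
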