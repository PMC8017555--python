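"""Configuration objects shared across the simulation and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ConfigurationError(ValueError):
    """Raised when a configuration value is out of its admissible range."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study generator.

    The defaults define the reference simulation conditions used throughout the
    test suite: an LD-structured genotype panel with one planted causal variant
    per locus, a 5 kb-binned cis contact map with power-law distance decay,
    multiplicative per-bin bias and planted loops, a packed gene annotation and
    a log-normal (log2-scale) tumor/normal expression matrix.

    Parameters
    ----------
    seed
        Base seed; every generator is a pure function of (config, seed).
    n_haplotypes
        Size of the founder haplotype pool from which individuals draw two
        haplotypes with replacement.
    adjacent_corr
        Target Pearson correlation between dosages of neighboring SNPs,
        realized by first-order Markov copying on the allele-frequency
        quantile scale.
    maf_range
        (low, high] range of founder minor-allele frequencies; low must be > 0.
    causal_effect
        Per-allele effect of the causal variant on a standardized quantitative
        trait.  ``None`` sizes the effect so the causal variant's expected
        marginal z-score equals ``target_z``.
    sequencing_depth
        Total expected cis contact count per simulated chromosome.
    decay_exponent
        Power-law exponent of contact probability vs genomic distance,
        p(d) ~ d**(-decay_exponent).
    bias_sd
        Standard deviation of the log-normal per-bin visibility bias.
    loop_fold
        Multiplier applied to the expected count of planted loop bin pairs.
    loop_gap_range
        (min, max) bp separation from which planted-loop anchor distances are
        drawn log-uniformly; must lie within the caller's [20 kb, 2 Mb] filter.
    overdispersion
        Gamma-Poisson overdispersion of contact counts (0 = exact Poisson).
    de_fraction, de_lfc
        Fraction of genes shifted in the tumor group and the log2 fold change.
    dup_fraction, trans_fraction, cis_short_fraction
        Composition of simulated valid-pair files, as fractions of all records.
    """

    seed: int = 0
    # genotypes / GWAS
    n_haplotypes: int = 2000
    n_snps_per_locus: int = 100
    n_loci: int = 5
    adjacent_corr: float = 0.6
    corr_block_range: tuple[float, float] | None = None
    corr_block_len: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_individuals: int = 5000
    causal_effect: float | None = None
    target_z: float = 6.0
    # contact map
    chrom_length: int = 2_000_000
    bin_resolution: int = 5000
    sequencing_depth: int = 1_000_000
    decay_exponent: float = 1.0
    bias_sd: float = 0.2
    loop_fold: float = 5.0
    n_planted_loops: int = 5
    loop_gap_range: tuple[int, int] = (20_000, 300_000)
    overdispersion: float = 0.0
    # genes / expression
    n_genes: int = 40
    gene_span_range: tuple[int, int] = (5_000, 30_000)
    n_tumor: int = 20
    n_normal: int = 20
    de_fraction: float = 0.1
    de_lfc: float = 2.0
    # valid-pair composition
    dup_fraction: float = 0.16
    trans_fraction: float = 0.11
    cis_short_fraction: float = 0.18

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < low < high <= 0.5, got {self.maf_range}"
            )
        if not (0.0 <= self.adjacent_corr < 1.0):
            raise ConfigurationError("adjacent_corr must lie in [0, 1)")
        if self.corr_block_range is not None:
            clo, chi = self.corr_block_range
            if not (0.0 <= clo <= chi < 1.0):
                raise ConfigurationError("corr_block_range must lie in [0, 1)")
            if self.corr_block_len < 1:
                raise ConfigurationError("corr_block_len must be >= 1")
        if self.n_haplotypes < 2:
            raise ConfigurationError("n_haplotypes must be >= 2")
        if self.n_snps_per_locus < 1:
            raise ConfigurationError("n_snps_per_locus must be >= 1")
        if self.bin_resolution <= 0:
            raise ConfigurationError("bin_resolution must be positive")
        if self.decay_exponent <= 0:
            raise ConfigurationError("decay_exponent must be > 0")
        if self.bias_sd < 0:
            raise ConfigurationError("bias_sd must be >= 0")
        if self.loop_fold < 1:
            raise ConfigurationError("loop_fold must be >= 1")
        if self.n_planted_loops < 0:
            raise ConfigurationError("n_planted_loops must be >= 0")
        glo, ghi = self.loop_gap_range
        if not (20_000 <= glo <= ghi <= 2_000_000):
            raise ConfigurationError(
                "loop_gap_range must lie within [20000, 2000000] bp"
            )
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        frac_sum = self.dup_fraction + self.trans_fraction + self.cis_short_fraction
        if min(self.dup_fraction, self.trans_fraction, self.cis_short_fraction) < 0:
            raise ConfigurationError("valid-pair fractions must be non-negative")
        if frac_sum > 1.0 + 1e-12:
            raise ConfigurationError("valid-pair fractions must sum to <= 1")


#: Field names of SimConfig, used to reject unknown keys in YAML configs.
_SIM_FIELDS = frozenset(f.name for f in fields(SimConfig))


def sim_config_from_dict(d: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a mapping, rejecting unknown keys."""
    unknown = set(d) - _SIM_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown SimConfig keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("maf_range", "loop_gap_range", "gene_span_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimConfig(**d)
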