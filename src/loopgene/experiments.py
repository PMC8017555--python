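"""Seeded simulation experiments measuring the pipeline's operating
characteristics: credible-set coverage, loop-caller error rates and power,
end-to-end link recovery, and heritability-enrichment recovery.

Each driver builds its inputs with :mod:`loopgene.synthetic` under the
reference study conditions, runs the corresponding analysis stage from
scratch, and returns summary numbers.  They are used both by the validation
test suite and by the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .annotation import GenomeAnnotation
from .enrichment import compute_ld_scores, fit_sldsc
from .finemap import FinemapConfig, fine_map, fine_map_locus
from .hichip import HiChIPLoopModel, merge_loops
from .synthetic import (
    effect_for_z,
    sim_contacts,
    sim_gwas_locus,
    sim_heritability_gwas,
    sim_panel,
    simulate_study,
)
from .variant2gene import map_cvs_to_targets

__all__ = [
    "credible_set_coverage",
    "loop_null_fdp",
    "loop_power",
    "link_recovery",
    "sldsc_recovery",
]


def credible_set_coverage(
    n_loci: int = 1_000,
    seed: int = 1,
    config: SimConfig | None = None,
    finemap_config: FinemapConfig | None = None,
) -> dict:
    """Fraction of simulated loci whose credible set contains the causal SNP.

    Per locus: a fresh LD-structured panel, one causal variant chosen
    uniformly, a quantitative GWAS with the effect sized for the configured
    expected |z| (default 6 at n = 5,000), marginal OLS statistics, and a
    credible set at the configured level.
    """
    cfg = config or SimConfig(seed=seed)
    fcfg = finemap_config or FinemapConfig()
    hits = 0
    sizes = []
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n_loci)):
        s_panel, s_gwas, s_pick = ss.spawn(3)
        panel = sim_panel(cfg, locus_id=f"cov{i}", seed=s_panel)
        causal = int(np.random.default_rng(s_pick).integers(panel.n_snps))
        effect = (
            cfg.causal_effect
            if cfg.causal_effect is not None
            else effect_for_z(cfg.target_z, panel.n_individuals, float(panel.maf[causal]))
        )
        stats = sim_gwas_locus(panel, causal, effect, seed=s_gwas)
        cs = fine_map_locus(stats, fcfg)
        hits += panel.variant_ids[causal] in cs
        sizes.append(len(cs))
    return {
        "coverage_pct": 100.0 * hits / n_loci,
        "n": n_loci,
        "level": fcfg.level,
        "median_set_size": float(np.median(sizes)),
    }


def loop_null_fdp(
    n_sims: int = 50,
    seed: int = 1,
    config: SimConfig | None = None,
    fdr: float = 0.01,
) -> dict:
    """Mean false-discovery proportion of the loop caller on null contact maps.

    Null maps carry decay and bias but no planted loops, so every discovery
    is false and FDP = 1{R > 0} per simulation.
    """
    cfg = config or SimConfig(seed=seed, n_planted_loops=0)
    fdps = []
    for ss in np.random.SeedSequence(seed).spawn(n_sims):
        bp, _ = sim_contacts(cfg, seed=ss)
        res = HiChIPLoopModel(bp, {"chrS1": cfg.chrom_length}).fit(fdr=fdr)
        r = len(res.loops)
        fdps.append(1.0 if r > 0 else 0.0)
    return {"mean_fdp": float(np.mean(fdps)), "n_sims": n_sims, "fdr": fdr}


def loop_power(
    n_sims: int = 20,
    seed: int = 2,
    config: SimConfig | None = None,
    fdr: float = 0.01,
) -> dict:
    """Recall of planted fold-5 loops at the default sequencing depth."""
    cfg = config or SimConfig(seed=seed)
    found = total = 0
    for ss in np.random.SeedSequence(seed).spawn(n_sims):
        bp, coords = sim_contacts(cfg, seed=ss)
        res = HiChIPLoopModel(bp, {"chrS1": cfg.chrom_length}).fit(fdr=fdr)
        called = set(
            zip(res.loops["start1"] // cfg.bin_resolution,
                res.loops["start2"] // cfg.bin_resolution)
        )
        for c in coords:
            total += 1
            found += (c["bin1"], c["bin2"]) in called
    return {
        "power": found / total if total else float("nan"),
        "n_planted": total,
        "loop_fold": cfg.loop_fold,
        "depth": cfg.sequencing_depth,
    }


def link_recovery(n_seeds: int = 20, base_seed: int = 1,
                  config: SimConfig | None = None) -> dict:
    """End-to-end recovery of planted variant->gene links.

    Per seed: simulate a full study, fine-map, call and merge loops from both
    cell lines, map credible variants through anchors, and check each planted
    link for presence in the link table.
    """
    from dataclasses import replace

    recovered = total = 0
    for k in range(n_seeds):
        cfg = replace(config or SimConfig(), seed=base_seed + k)
        study = simulate_study(cfg)
        css = fine_map(study.sumstats)
        loops = merge_loops(
            [
                HiChIPLoopModel(bp, study.chrom_sizes, source=cl).fit().loops
                for cl, bp in study.binpairs.items()
            ]
        )
        ann = GenomeAnnotation(study.genes, chrom_sizes=study.chrom_sizes)
        cvs = pd.concat([cs.members for cs in css.values()], ignore_index=True)
        links = map_cvs_to_targets(cvs, loops, ann)
        for pl in study.truth.planted_links:
            total += 1
            recovered += bool(
                (
                    (links["variant_id"] == pl["variant_id"])
                    & (links["gene_id"] == pl["gene_id"])
                ).any()
            )
    return {"recovery_pct": 100.0 * recovered / total, "n_links": total,
            "n_seeds": n_seeds}


def sldsc_recovery(
    n_reps: int = 50,
    seed: int = 11,
    m_snps: int = 2_000,
    n_samples: int = 2_000,
    category_fraction: float = 0.1,
    enrichment: float = 5.0,
    h2: float = 0.5,
    window_bp: int = 1_000_000,
) -> dict:
    """Mean estimated heritability enrichment for a planted enriched category.

    A block-LD reference panel (20,000 founder haplotypes over 20 Mb) scores
    the SNPs; each replicate draws summary statistics from the multivariate
    normal model with the masked category holding an ``enrichment``-fold
    share of h2, and fits the regression with the intercept constrained to 1
    (exact for this generating model).
    """
    cfg = SimConfig(
        seed=seed,
        n_snps_per_locus=m_snps,
        n_individuals=n_samples,
        n_haplotypes=20_000,
        chrom_length=10_000 * m_snps,
        corr_block_range=(0.1, 0.98),
    )
    panel = sim_panel(cfg, seed=seed)
    rng = np.random.default_rng(seed + 1)
    mask = np.zeros(m_snps, dtype=bool)
    mask[rng.choice(m_snps, int(round(category_fraction * m_snps)), replace=False)] = True
    annotations = np.column_stack([np.ones(m_snps), mask])
    ldscores = compute_ld_scores(panel.dosages, panel.positions, annotations, window_bp)
    estimates = []
    for ss in np.random.SeedSequence(seed + 2).spawn(n_reps):
        chisq = sim_heritability_gwas(panel, mask, h2=h2, enrichment=enrichment, seed=ss)
        res = fit_sldsc(
            chisq, ldscores, annotations, n_samples=n_samples,
            categories=["base", "loops"], constrain_intercept=True,
        )
        estimates.append(float(res.enrichment[1]))
    estimates = np.asarray(estimates)
    return {
        "mean_enrichment": float(estimates.mean()),
        "sd": float(estimates.std()),
        "n_reps": n_reps,
        "true_enrichment": enrichment,
    }
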