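"""Bayesian fine-mapping of GWAS loci from marginal summary statistics.

Each variant's evidence is the approximate Bayes factor computed from its
marginal effect estimate beta and standard error se under a normal prior
N(0, W) on the effect:

    ABF = sqrt(V / (V + W)) * exp(z**2 * W / (2 * (V + W))),   V = se**2

Under the single-causal-variant assumption with a flat prior over variants,
the posterior probability of variant i being causal is ABF_i / sum_j ABF_j.
The level-L credible set is the smallest pp-ranked prefix whose cumulative
posterior probability reaches L (default 0.99).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["FinemapConfig", "CredibleSet", "compute_abf", "log_abf", "fine_map_locus", "fine_map"]


@dataclass(frozen=True)
class FinemapConfig:
    """Prior effect variance W and credible level."""

    prior_var: float = 0.04
    level: float = 0.99

    def __post_init__(self) -> None:
        if self.prior_var < 0:
            raise ValueError("prior_var must be >= 0")
        if not (0.0 < self.level <= 1.0):
            raise ValueError("level must lie in (0, 1]")


def log_abf(beta, se, prior_var: float = 0.04):
    """Natural log of the approximate Bayes factor (vectorized).

    Working in logs keeps very large z-scores finite.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValueError("beta and se must be finite")
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_var < 0:
        raise ValueError("prior variance must be >= 0")
    v = se**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + prior_var)) + z2 * prior_var / (2.0 * (v + prior_var))


def compute_abf(beta, se, prior_var: float = 0.04):
    """Approximate Bayes factor for association of one variant (or an array).

    Strictly increasing in |z| for fixed se and prior_var > 0; equals 1
    identically under the degenerate prior W = 0.
    """
    return np.exp(log_abf(beta, se, prior_var))


@dataclass
class CredibleSet:
    """Per-locus fine-mapping result.

    ``table`` holds every variant of the locus with columns variant_id,
    chrom, pos, abf, pp, in_credible_set, sorted by pp descending (ties by
    chrom, pos, variant_id); ``members`` is the credible prefix.
    """

    locus_id: str
    table: pd.DataFrame
    level: float

    @property
    def members(self) -> pd.DataFrame:
        return self.table[self.table["in_credible_set"]]

    @property
    def variant_ids(self) -> list[str]:
        return self.members["variant_id"].tolist()

    @property
    def total_pp(self) -> float:
        return float(self.members["pp"].sum())

    def __len__(self) -> int:
        return int(self.table["in_credible_set"].sum())

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.variant_ids)


def fine_map_locus(records: pd.DataFrame, config: FinemapConfig = FinemapConfig()) -> CredibleSet:
    """Fine-map one locus: posterior probabilities and the credible set.

    ``records`` needs columns variant_id, beta, se and a single locus_id
    (chrom/pos are carried through when present).  Variants with missing beta
    or se are dropped with a warning.  Accumulation is inclusive: the set
    stops at the first member reaching the level.
    """
    if len(records) == 0:
        raise ValueError("cannot fine-map an empty locus")
    loci = records["locus_id"].unique() if "locus_id" in records else ["locus"]
    if len(loci) > 1:
        raise ValueError(f"records span multiple loci: {sorted(map(str, loci))}")
    locus_id = str(loci[0])

    df = records.copy()
    bad = df["beta"].isna() | df["se"].isna()
    if bad.any():
        logger.warning("locus %s: dropping %d variants with missing beta/se", locus_id, int(bad.sum()))
        df = df[~bad]
    if len(df) == 0:
        raise ValueError(f"locus {locus_id}: no variants with complete summary statistics")

    la = log_abf(df["beta"].to_numpy(), df["se"].to_numpy(), config.prior_var)
    # softmax in log space: pp_i = ABF_i / sum_j ABF_j
    la_shift = la - la.max()
    pp = np.exp(la_shift)
    pp /= pp.sum()
    df = df.assign(abf=np.exp(la), pp=pp)

    sort_cols = ["pp"] + [c for c in ("chrom", "pos", "variant_id") if c in df.columns]
    df = df.sort_values(sort_cols, ascending=[False] + [True] * (len(sort_cols) - 1), kind="mergesort")
    cum = df["pp"].cumsum()
    # first index where cumulative pp reaches the level (inclusive)
    reached = np.searchsorted(cum.to_numpy(), config.level - 1e-12) + 1
    n_keep = min(int(reached), len(df))
    df = df.assign(in_credible_set=np.arange(len(df)) < n_keep).reset_index(drop=True)
    keep_cols = [
        c for c in ("variant_id", "chrom", "pos", "beta", "se", "locus_id", "abf", "pp", "in_credible_set")
        if c in df.columns
    ]
    return CredibleSet(locus_id=locus_id, table=df[keep_cols], level=config.level)


def fine_map(records: pd.DataFrame, config: FinemapConfig = FinemapConfig()) -> dict[str, CredibleSet]:
    """Fine-map every locus in a summary-statistics frame (grouped by locus_id)."""
    return {
        str(locus): fine_map_locus(group, config)
        for locus, group in records.groupby("locus_id", sort=True)
    }
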