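"""HiChIP contact processing and loop calling.

Valid read pairs are QC-classified (duplicate / trans / cis-short /
cis-long), aggregated into 5 kb bin pairs, and tested for looping against a
distance-decay x coverage-bias background:

* the decay curve p(d) is estimated on equal-occupancy distance bins over the
  candidate pairs (zero-count pairs included) and made monotone non-increasing
  by pool-adjacent-violators;
* per-bin visibility bias b_i is the bin's marginal coverage over the mean
  coverage of nonzero bins;
* each candidate pair in [d_min, d_max] is scored with an upper-tail binomial
  p-value P(X >= k | N, pi_ij), pi_ij proportional to p(d_ij) * b_i * b_j
  with the total candidate mass preserved, followed by Benjamini-Hochberg
  adjustment over all candidates.

``HiChIPLoopModel`` wraps these stages as a fitted model whose
``LoopCallResults`` carries the significant loops, the background components
and a text summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "DecayModel",
    "BiasVector",
    "HiChIPLoopModel",
    "LoopCallResults",
    "qc_valid_pairs",
    "bin_pairs",
    "fit_distance_decay",
    "estimate_bias",
    "call_loops",
    "merge_loops",
]

DEFAULT_RESOLUTION = 5_000
DEFAULT_D_MIN = 20_000
DEFAULT_D_MAX = 2_000_000
DEFAULT_FDR = 0.01


# ---------------------------------------------------------------------------
# QC


@dataclass(frozen=True)
class QCReport:
    """Counts and percentages of valid-pair categories.

    Percentages are relative to ``total_valid``, so the three unique-category
    percentages sum to the unique percentage (the partition identity).
    """

    total_valid: int
    duplicates: int
    unique_valid: int
    cis_long: int
    cis_short: int
    trans: int

    def _pct(self, k: int) -> float:
        return 100.0 * k / self.total_valid

    @property
    def pct_unique(self) -> float:
        return self._pct(self.unique_valid)

    @property
    def pct_duplicates(self) -> float:
        return self._pct(self.duplicates)

    @property
    def pct_cis_long(self) -> float:
        return self._pct(self.cis_long)

    @property
    def pct_cis_short(self) -> float:
        return self._pct(self.cis_short)

    @property
    def pct_trans(self) -> float:
        return self._pct(self.trans)

    def to_dict(self) -> dict:
        return {
            "total_valid": self.total_valid,
            "duplicates": self.duplicates,
            "unique_valid": self.unique_valid,
            "cis_long": self.cis_long,
            "cis_short": self.cis_short,
            "trans": self.trans,
            "pct_unique": self.pct_unique,
            "pct_duplicates": self.pct_duplicates,
            "pct_cis_long": self.pct_cis_long,
            "pct_cis_short": self.pct_cis_short,
            "pct_trans": self.pct_trans,
        }


def qc_valid_pairs(pairs: pd.DataFrame, cis_cutoff: int = DEFAULT_D_MIN) -> QCReport:
    """Classify valid pairs into duplicate / trans / cis-long / cis-short.

    A duplicate is a record whose full coordinate/strand tuple repeats (the
    first occurrence is kept).  Among unique pairs: trans when chromosomes
    differ, cis-long when the separation exceeds ``cis_cutoff``, cis-short
    otherwise.
    """
    if len(pairs) == 0:
        raise ValueError("cannot QC an empty pair list")
    key_cols = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    dup_mask = pairs.duplicated(subset=key_cols, keep="first")
    unique = pairs[~dup_mask]
    trans_mask = unique["chrom1"] != unique["chrom2"]
    sep = (unique["pos2"] - unique["pos1"]).abs()
    cis_long = int(((~trans_mask) & (sep > cis_cutoff)).sum())
    cis_short = int(((~trans_mask) & (sep <= cis_cutoff)).sum())
    return QCReport(
        total_valid=len(pairs),
        duplicates=int(dup_mask.sum()),
        unique_valid=len(unique),
        cis_long=cis_long,
        cis_short=cis_short,
        trans=int(trans_mask.sum()),
    )


# ---------------------------------------------------------------------------
# binning


def bin_pairs(pairs: pd.DataFrame, resolution: int = DEFAULT_RESOLUTION) -> pd.DataFrame:
    """Aggregate unique cis pairs into per-chromosome bin-pair counts.

    Bin index = floor((pos - 1) / resolution); the pair is stored unordered
    (bin1 <= bin2).  Trans records are discarded with their count logged.
    Duplicates should be removed beforehand (see :func:`qc_valid_pairs`).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    trans = pairs["chrom1"] != pairs["chrom2"]
    if trans.any():
        logger.info("discarding %d trans pairs before binning", int(trans.sum()))
    cis = pairs[~trans]
    b1 = (cis["pos1"].to_numpy() - 1) // resolution
    b2 = (cis["pos2"].to_numpy() - 1) // resolution
    lo = np.minimum(b1, b2)
    hi = np.maximum(b1, b2)
    df = pd.DataFrame({"chrom": cis["chrom1"].to_numpy(), "bin1": lo, "bin2": hi})
    out = df.groupby(["chrom", "bin1", "bin2"], sort=True).size().reset_index(name="count")
    return out


def _candidates(
    binpairs: pd.DataFrame,
    chrom_sizes: dict[str, int],
    resolution: int,
    d_min: int,
    d_max: int,
) -> pd.DataFrame:
    """Enumerate all in-range cis bin pairs per chromosome with observed counts.

    The candidate universe includes observed-zero pairs so that multiplicity
    is accounted for properly.
    """
    frames = []
    gap_lo = max(1, int(np.ceil(d_min / resolution)))
    for chrom, size in sorted(chrom_sizes.items()):
        n_bins = size // resolution
        gap_hi = min(n_bins - 1, d_max // resolution)
        if gap_hi < gap_lo:
            continue
        ii = np.concatenate([np.arange(n_bins - g) for g in range(gap_lo, gap_hi + 1)])
        jj = np.concatenate([np.arange(n_bins - g) + g for g in range(gap_lo, gap_hi + 1)])
        frames.append(pd.DataFrame({"chrom": chrom, "bin1": ii, "bin2": jj}))
    if not frames:
        raise ValueError("no candidate bin pairs in the distance range")
    cand = pd.concat(frames, ignore_index=True)
    cand = cand.merge(binpairs, on=["chrom", "bin1", "bin2"], how="left")
    cand["count"] = cand["count"].fillna(0).astype(np.int64)
    cand["distance"] = (cand["bin2"] - cand["bin1"]) * resolution
    return cand


# ---------------------------------------------------------------------------
# background model


@dataclass
class DecayModel:
    """Monotone contact-probability-vs-distance curve on equal-occupancy bins.

    ``prob(d)`` interpolates the per-pair contact probability (fraction of
    total counts expected for a single pair at distance d); it is
    non-increasing in d and clamped to the fitted range.
    """

    distances: np.ndarray  # representative distance per occupancy bin
    probs: np.ndarray  # isotonic per-pair probability per bin
    n_pairs: np.ndarray  # candidate pairs per bin
    total_count: int

    def prob(self, d) -> np.ndarray:
        """Per-pair contact probability at distance d.

        Interpolates in log-log space (exact for power-law decay) and
        extrapolates the first/last segment slopes beyond the fitted bin
        medians, so the steep short-distance end is not flattened by edge
        clipping.  Monotone non-increasing by construction.
        """
        d = np.atleast_1d(np.asarray(d, dtype=float))
        x = np.log(np.maximum(self.distances, 1.0))
        y = np.log(np.maximum(self.probs, 1e-300))
        q = np.log(np.maximum(d, 1.0))
        out = np.interp(q, x, y)
        if len(x) >= 2:
            left = q < x[0]
            if left.any() and x[1] > x[0]:
                slope = (y[1] - y[0]) / (x[1] - x[0])
                out[left] = y[0] + slope * (q[left] - x[0])
            right = q > x[-1]
            if right.any() and x[-1] > x[-2]:
                slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
                out[right] = y[-1] + slope * (q[right] - x[-1])
        return np.exp(out)


def fit_distance_decay(
    binpairs: pd.DataFrame,
    chrom_sizes: dict[str, int],
    resolution: int = DEFAULT_RESOLUTION,
    n_distance_bins: int = 200,
    d_min: int = DEFAULT_D_MIN,
    d_max: int = DEFAULT_D_MAX,
) -> DecayModel:
    """Fit the distance-decay background over in-range candidate pairs.

    Candidates (including zero-count pairs) are partitioned into
    ``n_distance_bins`` distance bins of approximately equal pair counts; the
    raw per-pair probability in a bin is (sum of counts) / (total counts *
    pairs in bin), then pool-adjacent-violators enforces monotone
    non-increase, weighting each bin by its pair count.
    """
    cand = _candidates(binpairs, chrom_sizes, resolution, d_min, d_max)
    return _fit_decay_from_candidates(cand, n_distance_bins)


def _fit_decay_from_candidates(cand: pd.DataFrame, n_distance_bins: int) -> DecayModel:
    cand = cand.sort_values("distance", kind="mergesort").reset_index(drop=True)
    total = int(cand["count"].sum())
    n = len(cand)
    n_bins = max(1, min(n_distance_bins, n))
    # equal-occupancy split by candidate-pair rank, distance ties kept together
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    bin_of = np.zeros(n, dtype=int)
    for b in range(n_bins):
        bin_of[edges[b] : edges[b + 1]] = b
    grp = cand.groupby(bin_of)
    ksum = grp["count"].sum().to_numpy()
    npairs = grp.size().to_numpy()
    dmed = grp["distance"].median().to_numpy()
    if total == 0:
        logger.warning("all candidate counts are zero; returning a flat decay model")
        probs = np.full(len(dmed), 1.0 / n)
        return DecayModel(distances=dmed, probs=probs, n_pairs=npairs, total_count=0)
    raw = ksum / (total * npairs)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    probs = iso.fit_transform(dmed, raw, sample_weight=npairs)
    return DecayModel(distances=dmed, probs=probs, n_pairs=npairs, total_count=total)


@dataclass
class BiasVector:
    """Per-bin multiplicative visibility bias, mean 1 over covered bins."""

    values: dict[str, np.ndarray]  # chrom -> per-bin bias (0 where no coverage)

    def get(self, chrom: str, bins: np.ndarray) -> np.ndarray:
        return self.values[chrom][bins]

    @property
    def nonzero_mean(self) -> float:
        allv = np.concatenate([v for v in self.values.values()])
        nz = allv[allv > 0]
        return float(nz.mean()) if len(nz) else float("nan")


def estimate_bias(
    binpairs: pd.DataFrame,
    chrom_sizes: dict[str, int],
    resolution: int = DEFAULT_RESOLUTION,
    decay: DecayModel | None = None,
    d_min: int = DEFAULT_D_MIN,
    d_max: int = DEFAULT_D_MAX,
    n_iter: int = 5,
) -> BiasVector:
    """Per-bin visibility bias from marginal coverage.

    Without a decay model this is the raw coverage ratio (bin coverage over
    the nonzero-bin mean).  With one, the coverage is normalized by the
    bin's expected coverage under the decay background,
    ``E_i = sum_j p(d_ij) * b_j`` over candidate partners, iterated to a
    fixed point — the marginal constraint of the Poisson background.  This
    matters near chromosome ends, where raw coverage under-represents
    visibility because edge bins simply have fewer candidate partners.

    Bins with zero coverage get bias 0 and are excluded from loop testing.
    The mean over covered bins is normalized to 1.
    """
    if len(binpairs) == 0:
        raise ValueError("cannot estimate bias from an empty contact list")
    cov: dict[str, np.ndarray] = {
        chrom: np.zeros(size // resolution) for chrom, size in chrom_sizes.items()
    }
    for chrom, sub in binpairs.groupby("chrom"):
        np.add.at(cov[chrom], sub["bin1"].to_numpy(), sub["count"].to_numpy())
        np.add.at(cov[chrom], sub["bin2"].to_numpy(), sub["count"].to_numpy())

    def _normalized(values: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        allv = np.concatenate(list(values.values()))
        nz = allv[allv > 0]
        mean = nz.mean() if len(nz) else 1.0
        return {c: v / mean for c, v in values.items()}

    if decay is None:
        return BiasVector(values=_normalized(cov))

    cand = _candidates(binpairs, chrom_sizes, resolution, d_min, d_max)
    pd_decay = decay.prob(cand["distance"].to_numpy())
    bias = {c: (v > 0).astype(float) for c, v in cov.items()}
    for _ in range(n_iter):
        expected = {c: np.zeros_like(v) for c, v in cov.items()}
        for chrom, sub in cand.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            b1 = sub["bin1"].to_numpy()
            b2 = sub["bin2"].to_numpy()
            p = pd_decay[idx]
            np.add.at(expected[chrom], b1, p * bias[chrom][b2])
            np.add.at(expected[chrom], b2, p * bias[chrom][b1])
        new = {}
        for chrom, v in cov.items():
            e = expected[chrom]
            with np.errstate(divide="ignore", invalid="ignore"):
                b = np.where((v > 0) & (e > 0), v / np.maximum(e, 1e-300), 0.0)
            new[chrom] = b
        bias = _normalized(new)
    return BiasVector(values=bias)


# ---------------------------------------------------------------------------
# loop calling


def call_loops(
    binpairs: pd.DataFrame,
    decay: DecayModel,
    bias: BiasVector,
    chrom_sizes: dict[str, int],
    resolution: int = DEFAULT_RESOLUTION,
    d_min: int = DEFAULT_D_MIN,
    d_max: int = DEFAULT_D_MAX,
    fdr: float = DEFAULT_FDR,
    source: str = "sample",
    return_candidates: bool = False,
):
    """Call FDR-significant loops against the decay x bias background.

    Expected probability of candidate (i, j):
    ``pi_ij = p(d_ij) * b_i * b_j / Z`` with Z preserving the total candidate
    probability mass; p-value is the binomial upper tail
    P(X >= k | N = total counts, pi_ij), BH-adjusted over all candidates with
    nonzero expected probability.  Loops are candidates with q <= fdr and
    k > 0, reported as one-bin anchors in half-open coordinates.
    """
    if not (0.0 < fdr <= 1.0):
        raise ValueError("fdr must lie in (0, 1]")
    cand = _candidates(binpairs, chrom_sizes, resolution, d_min, d_max)
    cand = cand.sort_values(["chrom", "bin1", "bin2"], kind="mergesort").reset_index(drop=True)
    total = int(binpairs["count"].sum())
    p_decay = decay.prob(cand["distance"].to_numpy())
    b1 = np.empty(len(cand))
    b2 = np.empty(len(cand))
    for chrom, sub in cand.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        b1[idx] = bias.get(chrom, sub["bin1"].to_numpy())
        b2[idx] = bias.get(chrom, sub["bin2"].to_numpy())
    pi = p_decay * b1 * b2
    testable = pi > 0
    mass = pi[testable].sum()
    if mass > 0:
        pi = pi * (p_decay[testable].sum() / mass)
    pi = np.clip(pi, 0.0, 1.0)

    pval = np.ones(len(cand))
    k = cand["count"].to_numpy()
    if total > 0:
        pval[testable] = stats.binom.sf(k[testable] - 1, total, pi[testable])
    qval = np.ones(len(cand))
    if testable.any():
        qval[testable] = multipletests(pval[testable], method="fdr_bh")[1]

    cand["expected"] = total * pi
    cand["p_value"] = pval
    cand["q_value"] = qval
    sig = cand[(cand["q_value"] <= fdr) & (cand["count"] > 0)].copy()
    loops = pd.DataFrame(
        {
            "chrom1": sig["chrom"],
            "start1": sig["bin1"] * resolution,
            "end1": (sig["bin1"] + 1) * resolution,
            "chrom2": sig["chrom"],
            "start2": sig["bin2"] * resolution,
            "end2": (sig["bin2"] + 1) * resolution,
            "count": sig["count"],
            "expected": sig["expected"],
            "p_value": sig["p_value"],
            "q_value": sig["q_value"],
            "distance": sig["distance"],
            "source": source,
        }
    ).reset_index(drop=True)
    if return_candidates:
        return loops, cand
    return loops


def merge_loops(loop_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union loop tables from several cell lines, merging bin-identical loops.

    Loops whose two anchors coincide exactly are collapsed into one record
    carrying all source labels (comma-joined, sorted) and the minimum q.
    Mixing resolutions (anchor widths) raises.
    """
    if not loop_sets:
        return pd.DataFrame(
            columns=[
                "chrom1", "start1", "end1", "chrom2", "start2", "end2",
                "count", "expected", "p_value", "q_value", "distance", "source",
            ]
        )
    allloops = pd.concat(loop_sets, ignore_index=True)
    if len(allloops) == 0:
        return allloops
    widths = set((allloops["end1"] - allloops["start1"]).unique()) | set(
        (allloops["end2"] - allloops["start2"]).unique()
    )
    if len(widths) > 1:
        raise ValueError(f"cannot merge loops of mixed resolutions: {sorted(widths)}")

    keys = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    best = (
        allloops.sort_values("q_value", kind="mergesort")
        .drop_duplicates(subset=keys, keep="first")
        .set_index(keys)
    )
    grouped = allloops.groupby(keys, sort=True)
    best["source"] = grouped["source"].agg(
        lambda s: ",".join(sorted({x for row in s for x in str(row).split(",")}))
    )
    best["count"] = grouped["count"].max()
    merged = best.reset_index().sort_values(keys, kind="mergesort").reset_index(drop=True)
    return merged[allloops.columns]


# ---------------------------------------------------------------------------
# model / results wrappers


class HiChIPLoopModel:
    """Loop-calling model over binned cis contacts of one sample.

    Parameters
    ----------
    binpairs
        Frame (chrom, bin1, bin2, count) of unique cis contacts.
    chrom_sizes
        Mapping chromosome -> length in bp (defines the candidate universe).
    resolution, d_min, d_max
        Bin width and the anchor-separation filter, bp.
    """

    def __init__(
        self,
        binpairs: pd.DataFrame,
        chrom_sizes: dict[str, int],
        resolution: int = DEFAULT_RESOLUTION,
        d_min: int = DEFAULT_D_MIN,
        d_max: int = DEFAULT_D_MAX,
        source: str = "sample",
    ):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.binpairs = binpairs
        self.chrom_sizes = dict(chrom_sizes)
        self.resolution = resolution
        self.d_min = d_min
        self.d_max = d_max
        self.source = source

    def fit(self, n_distance_bins: int = 200, fdr: float = DEFAULT_FDR) -> "LoopCallResults":
        decay = fit_distance_decay(
            self.binpairs, self.chrom_sizes, self.resolution,
            n_distance_bins, self.d_min, self.d_max,
        )
        bias = estimate_bias(
            self.binpairs, self.chrom_sizes, self.resolution,
            decay=decay, d_min=self.d_min, d_max=self.d_max,
        )
        loops, cand = call_loops(
            self.binpairs, decay, bias, self.chrom_sizes, self.resolution,
            self.d_min, self.d_max, fdr, source=self.source, return_candidates=True,
        )
        return LoopCallResults(
            model=self, decay=decay, bias=bias, loops=loops,
            n_candidates=len(cand), fdr=fdr,
        )


@dataclass
class LoopCallResults:
    """Fitted background and the FDR-significant loops of one sample."""

    model: HiChIPLoopModel
    decay: DecayModel
    bias: BiasVector
    loops: pd.DataFrame
    n_candidates: int
    fdr: float

    def summary(self) -> str:
        lines = [
            f"HiChIP loop calling ({self.model.source})",
            f"  resolution          : {self.model.resolution} bp",
            f"  distance filter     : [{self.model.d_min}, {self.model.d_max}] bp",
            f"  candidate bin pairs : {self.n_candidates}",
            f"  total cis contacts  : {int(self.model.binpairs['count'].sum())}",
            f"  FDR threshold       : {self.fdr}",
            f"  significant loops   : {len(self.loops)}",
        ]
        if len(self.loops):
            lines.append(f"  median loop distance: {int(self.loops['distance'].median())} bp")
            lines.append(f"  mean loop distance  : {self.loops['distance'].mean():.0f} bp")
        return "\n".join(lines)
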