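"""Enrichment statistics: stratified LD-score regression and ssGSEA.

The heritability-enrichment core regresses GWAS chi-square statistics on
annotation-stratified LD scores:

    E[chi2_j] = 1 + intercept_dev + sum_c coef_c * N * l_j(c) / M

with l_j(c) = sum_k r2_adj(j,k) * a_c(k) over a bp window and
r2_adj = r2 - (1 - r2)/(n - 2).  Per-category heritability is accumulated
from the per-SNP contributions tau_c = coef_c / M and enrichment is
(h2_c / h2) / (M_c / M), with a block-jackknife standard error.

ssGSEA computes a per-sample enrichment score from the weighted running sum
over the sample's expression ranking (hit weights rank**alpha), normalized
across samples by the score range — invariant under any strictly increasing
transform of a sample's values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "compute_ld_scores",
    "StratifiedLDScore",
    "SLDSCResults",
    "fit_sldsc",
    "ssgsea",
    "ssgsea_matrix",
    "diff_expression",
]


# ---------------------------------------------------------------------------
# LD scores


def compute_ld_scores(
    dosages: np.ndarray,
    positions: np.ndarray,
    annotations: pd.DataFrame | np.ndarray,
    window_bp: int = 1_000_000,
) -> np.ndarray:
    """Annotation-stratified LD scores from a genotype panel.

    ``annotations`` is SNPs x categories binary membership whose first (or
    'base') column must cover all SNPs.  The self term is included, so an
    isolated SNP has base score exactly 1 (r2 = 1 has zero adjustment).
    """
    X = np.asarray(dosages, dtype=float)
    n, m = X.shape
    if n <= 3:
        raise ValueError("need more than 3 individuals for adjusted r2")
    if window_bp < 0:
        raise ValueError("window must be >= 0")
    A = annotations.to_numpy() if isinstance(annotations, pd.DataFrame) else np.asarray(annotations)
    A = A.astype(float)
    if A.shape[0] != m:
        raise ValueError("annotation rows must match SNP count")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("panel contains monomorphic SNPs; filter them first")
    Z = (X - X.mean(axis=0)) / sd
    pos = np.asarray(positions)
    scores = np.zeros((m, A.shape[1]))
    lo = np.searchsorted(pos, pos - window_bp, side="left")
    hi = np.searchsorted(pos, pos + window_bp, side="right")
    for j in range(m):
        nb = slice(lo[j], hi[j])
        r = Z[:, nb].T @ Z[:, j] / n
        r2 = r * r
        r2_adj = r2 - (1.0 - r2) / (n - 2)
        scores[j] = r2_adj @ A[nb]
    return scores


# ---------------------------------------------------------------------------
# stratified LD-score regression


@dataclass
class SLDSCResults:
    """Estimates of the stratified LD-score regression.

    ``enrichment`` is (h2_c / h2_total) / (M_c / M_total) per category, with
    block-jackknife standard errors; a base-only model has enrichment
    identically 1.
    """

    categories: list[str]
    coef: np.ndarray  # regression coefficients per category (M * tau_c)
    tau: np.ndarray  # per-SNP heritability contribution per category
    intercept: float
    h2: np.ndarray  # heritability attributed to each category
    h2_total: float
    m_category: np.ndarray
    m_total: int
    enrichment: np.ndarray
    enrichment_se: np.ndarray

    def summary(self) -> str:
        lines = [
            "Stratified LD-score regression",
            f"  SNPs: {self.m_total}   intercept: {self.intercept:.4f}   "
            f"h2 (base): {self.h2_total:.4f}",
            f"  {'category':<20}{'M_c':>8}{'tau':>12}{'h2_c':>10}{'enrich':>9}{'SE':>8}",
        ]
        for i, c in enumerate(self.categories):
            lines.append(
                f"  {c:<20}{int(self.m_category[i]):>8}{self.tau[i]:>12.3e}"
                f"{self.h2[i]:>10.4f}{self.enrichment[i]:>9.3f}{self.enrichment_se[i]:>8.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "categories": self.categories,
            "intercept": self.intercept,
            "h2_total": self.h2_total,
            "h2": self.h2.tolist(),
            "enrichment": self.enrichment.tolist(),
            "enrichment_se": self.enrichment_se.tolist(),
        }


class StratifiedLDScore:
    """Model object for the stratified LD-score regression.

    Parameters
    ----------
    chisq
        One GWAS chi-square statistic per scored SNP.
    ldscores
        SNPs x categories LD-score matrix from :func:`compute_ld_scores`.
    annotations
        SNPs x categories binary membership (base column covers all SNPs).
    n_samples
        GWAS sample size N.
    """

    def __init__(self, chisq, ldscores, annotations, n_samples: int,
                 categories: list[str] | None = None):
        self.chisq = np.asarray(chisq, dtype=float)
        self.ldscores = np.asarray(ldscores, dtype=float)
        A = annotations.to_numpy() if isinstance(annotations, pd.DataFrame) else np.asarray(annotations)
        self.annotations = A.astype(float)
        if categories is None:
            if isinstance(annotations, pd.DataFrame):
                categories = list(annotations.columns)
            else:
                categories = [f"c{k}" for k in range(A.shape[1])]
        self.categories = list(categories)
        self.n_samples = int(n_samples)
        m = len(self.chisq)
        if self.ldscores.shape != (m, A.shape[1]):
            raise ValueError("chisq, ldscores and annotations are inconsistent")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        base = self.annotations[:, 0]
        if not np.all(base == 1):
            raise ValueError("first annotation column must be the all-ones base category")

    def _weights(self) -> np.ndarray:
        """LD- and heteroskedasticity-correcting regression weights.

        1/l_base downweights SNPs whose chi-square is correlated with many
        neighbors; the squared term 1/(1 + N h2_agg l/M)^2 downweights SNPs
        with large expected chi-square (variance ~ 2 E[chi2]^2), using the
        aggregate heritability estimate for the expectation.
        """
        l_base = np.maximum(self.ldscores[:, 0], 1.0)
        m_total = self.annotations.shape[0]
        h2_agg = m_total * max(self.chisq.mean() - 1.0, 0.0) / (
            self.n_samples * self.ldscores[:, 0].mean()
        )
        het = 1.0 + self.n_samples * h2_agg * l_base / m_total
        return 1.0 / (l_base * het**2)

    def _solve(self, keep: np.ndarray, constrain_intercept: bool = False) -> tuple[np.ndarray, float]:
        """WLS fit on a SNP subset; returns (coefs per category, intercept)."""
        m_total = self.annotations.shape[0]
        X = self.n_samples * self.ldscores[keep] / m_total
        y = self.chisq[keep]
        w = self._weights()[keep]
        sw = np.sqrt(w)
        if constrain_intercept:
            design = X * sw[:, None]
            coef, _, rank, _ = np.linalg.lstsq(design, (y - 1.0) * sw, rcond=None)
            coef = np.concatenate([[1.0], coef])
        else:
            design = np.column_stack([np.ones(len(y)), X]) * sw[:, None]
            coef, _, rank, _ = np.linalg.lstsq(design, y * sw, rcond=None)
        if rank < design.shape[1]:
            corr = np.corrcoef(X, rowvar=False)
            pairs = [
                (self.categories[a], self.categories[b])
                for a in range(corr.shape[0])
                for b in range(a + 1, corr.shape[0])
                if abs(corr[a, b]) > 0.999
            ]
            raise np.linalg.LinAlgError(
                f"singular regression design; collinear categories: {pairs or self.categories}"
            )
        return coef[1:], float(coef[0])

    # note: with constrain_intercept the returned intercept is exactly 1.0

    def _enrichment(self, coef: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        m_total = self.annotations.shape[0]
        tau = coef / m_total
        per_snp_h2 = self.annotations @ tau
        h2 = self.annotations.T @ per_snp_h2  # h2_c = sum over SNPs in c
        h2_total = float(h2[0])
        m_c = self.annotations.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            enr = (h2 / h2_total) / (m_c / m_total)
        return enr, h2, h2_total

    def fit(self, n_blocks: int = 20, constrain_intercept: bool = False) -> SLDSCResults:
        """Fit the regression; ``constrain_intercept`` fixes the intercept at 1.

        Constraining is appropriate when confounding is known absent (e.g.
        simulated statistics); it stabilizes the heritability denominator of
        the enrichment ratio when the SNP count is small.
        """
        m = len(self.chisq)
        keep_all = np.ones(m, dtype=bool)
        coef, intercept = self._solve(keep_all, constrain_intercept)
        enr, h2, h2_total = self._enrichment(coef)
        m_c = self.annotations.sum(axis=0)
        m_total = self.annotations.shape[0]

        n_blocks = max(2, min(n_blocks, m))
        edges = np.linspace(0, m, n_blocks + 1).astype(int)
        jack = []
        for b in range(n_blocks):
            keep = np.ones(m, dtype=bool)
            keep[edges[b] : edges[b + 1]] = False
            coef_b, _ = self._solve(keep, constrain_intercept)
            jack.append(self._enrichment(coef_b)[0])
        jack = np.array(jack)
        with np.errstate(invalid="ignore"):
            se = np.sqrt((n_blocks - 1) / n_blocks * ((jack - jack.mean(axis=0)) ** 2).sum(axis=0))
        return SLDSCResults(
            categories=self.categories,
            coef=coef,
            tau=coef / m_total,
            intercept=intercept,
            h2=h2,
            h2_total=h2_total,
            m_category=m_c,
            m_total=m_total,
            enrichment=enr,
            enrichment_se=se,
        )


def fit_sldsc(chisq, ldscores, annotations, n_samples: int,
              n_blocks: int = 20, categories: list[str] | None = None,
              constrain_intercept: bool = False) -> SLDSCResults:
    """One-call wrapper around :class:`StratifiedLDScore`."""
    return StratifiedLDScore(chisq, ldscores, annotations, n_samples, categories).fit(
        n_blocks, constrain_intercept
    )


# ---------------------------------------------------------------------------
# ssGSEA


def ssgsea(values, genes, gene_set, alpha: float = 0.25) -> float:
    """Single-sample gene-set enrichment score of one expression profile.

    Genes are ranked by expression descending (ties broken by gene name for
    determinism); walking down the ranking, the score is the sum over
    positions of (cumulative hit weight fraction - cumulative miss fraction),
    where a hit's weight is its rank statistic (m for the top gene down to 1)
    raised to ``alpha`` and every miss counts 1/(m - |S|).  Depends on the
    ranking only.
    """
    values = np.asarray(values, dtype=float)
    genes = list(genes)
    m = len(genes)
    if m != len(values):
        raise ValueError("values and genes differ in length")
    gene_set = {str(g) for g in gene_set}
    if not gene_set:
        raise ValueError("gene_set is empty")
    hits_named = gene_set & set(map(str, genes))
    if not hits_named:
        raise ValueError("gene_set shares no genes with the profile")
    if len(hits_named) == m:
        raise ValueError("gene_set must be a proper subset of the profile")
    order = sorted(range(m), key=lambda i: (-values[i], str(genes[i])))
    rank_stat = np.arange(m, 0, -1, dtype=float)  # m..1 down the ranking
    is_hit = np.fromiter((str(genes[i]) in gene_set for i in order), bool, m)
    w = np.where(is_hit, rank_stat**alpha, 0.0)
    hit_cum = np.cumsum(w) / w.sum()
    miss_cum = np.cumsum(~is_hit) / (m - is_hit.sum())
    return float(np.sum(hit_cum - miss_cum))


def ssgsea_matrix(
    expression: pd.DataFrame,
    gene_set,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.Series:
    """Per-sample ssGSEA scores over a genes x samples matrix.

    With ``normalize`` the scores are divided by their range across samples
    (max - min), the usual cross-sample normalization.
    """
    genes = list(expression.index)
    scores = pd.Series(
        {
            sample: ssgsea(expression[sample].to_numpy(), genes, gene_set, alpha)
            for sample in expression.columns
        },
        name="es",
    )
    if normalize:
        rng = scores.max() - scores.min()
        if rng > 0:
            scores = scores / rng
    return scores


# ---------------------------------------------------------------------------
# differential expression


def diff_expression(
    expression: pd.DataFrame,
    labels: pd.Series,
    group_a: str = "tumor",
    group_b: str = "normal",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per gene between two sample groups, BH-adjusted.

    Returns a frame indexed by gene with columns t, p_value, q_value,
    log2fc (mean_a - mean_b), significant (q < alpha) and undefined (True for
    genes with zero variance in both groups, excluded from adjustment).
    """
    cols_a = labels.index[labels == group_a]
    cols_b = labels.index[labels == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 samples per group")
    A = expression[cols_a].to_numpy(dtype=float)
    B = expression[cols_b].to_numpy(dtype=float)
    undefined = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    t = np.where(undefined, np.nan, t)
    p = np.where(undefined, np.nan, p)
    q = np.full(len(p), np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if undefined.any():
        logger.warning("%d genes have zero variance in both groups", int(undefined.sum()))
    return pd.DataFrame(
        {
            "t": t,
            "p_value": p,
            "q_value": q,
            "log2fc": A.mean(axis=1) - B.mean(axis=1),
            "significant": (q < alpha) & ok,
            "undefined": undefined,
        },
        index=expression.index,
    )
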