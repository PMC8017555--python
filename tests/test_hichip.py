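"""QC classification, binning, background fitting and loop calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from loopgene.config import SimConfig
from loopgene import synthetic as syn
from loopgene.hichip import (
    HiChIPLoopModel,
    bin_pairs,
    call_loops,
    estimate_bias,
    fit_distance_decay,
    merge_loops,
    qc_valid_pairs,
)
from conftest import make_loops


def binom_sf_oracle(k: int, n: int, p: float) -> float:
    """Upper-tail binomial P(X >= k) by direct log-pmf summation.

    Independent of scipy's sf: accumulates exp(log C(n,x) + x log p +
    (n-x) log(1-p)) from x = k upward until terms vanish.
    """
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    total = 0.0
    for x in range(k, n + 1):
        logpmf = (
            math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
            + x * math.log(p) + (n - x) * math.log1p(-p)
        )
        term = math.exp(logpmf)
        total += term
        if term < total * 1e-17 and x > n * p:
            break
    return min(total, 1.0)


def _pairs(rows):
    return pd.DataFrame(
        rows, columns=["read_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    )


class TestQC:
    def test_hand_counted_fixture(self):
        """10 pairs: 2 exact duplicates, 4 cis>20kb, 2 cis<=20kb, 2 trans."""
        rows = [
            ("r1", "chr1", 100, "+", "chr1", 50_000, "-"),
            ("r2", "chr1", 100, "+", "chr1", 50_000, "-"),  # duplicate of r1
            ("r3", "chr1", 200, "+", "chr1", 90_000, "+"),
            ("r4", "chr1", 300, "-", "chr1", 120_000, "+"),
            ("r5", "chr1", 400, "+", "chr1", 425_000, "-"),
            ("r6", "chr1", 500, "+", "chr1", 5_000, "-"),
            ("r7", "chr1", 600, "-", "chr1", 20_600, "+"),
            ("r8", "chr1", 700, "+", "chr2", 700, "+"),
            ("r9", "chr1", 800, "-", "chr2", 900, "-"),
            ("r10", "chr1", 800, "-", "chr2", 900, "-"),  # duplicate of r9
        ]
        qc = qc_valid_pairs(_pairs(rows))
        assert (qc.total_valid, qc.duplicates, qc.unique_valid) == (10, 2, 8)
        assert (qc.cis_long, qc.cis_short, qc.trans) == (4, 2, 2)
        assert qc.pct_cis_long == pytest.approx(40.0)
        assert qc.pct_cis_short == pytest.approx(20.0)
        assert qc.pct_trans == pytest.approx(20.0)
        assert qc.pct_unique == pytest.approx(80.0)

    def test_all_trans(self):
        rows = [(f"r{i}", "chr1", 100 + i, "+", "chr2", 200 + i, "+") for i in range(5)]
        qc = qc_valid_pairs(_pairs(rows))
        assert qc.pct_cis_long == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qc_valid_pairs(_pairs([]))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(
        st.tuples(st.sampled_from(["chr1", "chr2"]), st.integers(1, 100),
                  st.sampled_from(["chr1", "chr2"]), st.integers(1, 60_000)),
        min_size=1, max_size=40,
    ))
    def test_partition_identity(self, raw):
        """Category percentages always sum to the unique percentage."""
        rows = [(f"r{i}", c1, p1, "+", c2, p2, "-") for i, (c1, p1, c2, p2) in enumerate(raw)]
        qc = qc_valid_pairs(_pairs(rows))
        assert qc.duplicates + qc.unique_valid == qc.total_valid
        assert qc.cis_long + qc.cis_short + qc.trans == qc.unique_valid
        assert qc.pct_cis_long + qc.pct_cis_short + qc.pct_trans == pytest.approx(qc.pct_unique)


class TestBinning:
    def test_boundary_convention(self):
        rows = [("r1", "chr1", 1, "+", "chr1", 5_000, "+"),
                ("r2", "chr1", 5_001, "+", "chr1", 10_000, "+")]
        bp = bin_pairs(_pairs(rows))
        assert bp.iloc[0][["bin1", "bin2"]].tolist() == [0, 0]
        assert bp.iloc[1][["bin1", "bin2"]].tolist() == [1, 1]

    def test_aggregation(self):
        rows = [("r1", "chr1", 100, "+", "chr1", 30_100, "+"),
                ("r2", "chr1", 200, "-", "chr1", 30_200, "-")]
        bp = bin_pairs(_pairs(rows))
        assert len(bp) == 1
        assert bp.iloc[0]["count"] == 2

    def test_hand_computed_bins_and_distance(self):
        rows = [("r1", "chr1", 12_000, "+", "chr1", 33_000, "+")]
        bp = bin_pairs(_pairs(rows))
        assert bp.iloc[0][["bin1", "bin2"]].tolist() == [2, 6]
        assert (bp.iloc[0]["bin2"] - bp.iloc[0]["bin1"]) * 5_000 == 20_000

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            bin_pairs(_pairs([("r1", "chr1", 1, "+", "chr1", 2, "+")]), resolution=0)


CHROM = {"chrS1": 2_000_000}


class TestDecay:
    def test_constant_counts_give_flat_curve(self):
        rows = []
        for i in range(0, 396):
            rows.append(("chrS1", i, i + 4, 7))
        bp = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "count"])
        decay = fit_distance_decay(bp, CHROM, n_distance_bins=20)
        # only d=20kb pairs observed, rest zero: prob flat within occupancy bins
        qs = decay.prob(np.linspace(20_000, 2_000_000, 50))
        assert (np.diff(qs) <= 1e-15).all()

    def test_power_law_slope_recovered(self):
        cfg = SimConfig(seed=1, decay_exponent=1.0, n_planted_loops=0, bias_sd=0.0)
        bp, _ = syn.sim_contacts(cfg, seed=1)
        decay = fit_distance_decay(bp, CHROM)
        d = decay.distances
        mask = (d > 25_000) & (d < 1_000_000) & (decay.probs > 0)
        slope = np.polyfit(np.log(d[mask]), np.log(decay.probs[mask]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_monotone_non_increasing_everywhere(self):
        cfg = SimConfig(seed=2, n_planted_loops=3)
        bp, _ = syn.sim_contacts(cfg, seed=2)
        decay = fit_distance_decay(bp, CHROM)
        qs = decay.prob(np.linspace(20_000, 2_000_000, 500))
        assert (np.diff(qs) <= 1e-15).all()

    def test_all_zero_counts_flat_with_warning(self, caplog):
        bp = pd.DataFrame({"chrom": ["chrS1"], "bin1": [0], "bin2": [10], "count": [0]})
        with caplog.at_level("WARNING"):
            decay = fit_distance_decay(bp, CHROM, n_distance_bins=5)
        assert "flat" in caplog.text
        assert len(set(np.round(decay.probs, 15))) == 1


class TestBias:
    def test_uniform_coverage_gives_unit_bias(self):
        rows = [("chrS1", i, i + 200, 5) for i in range(200)]  # every bin exactly once
        bp = pd.DataFrame(rows, columns=["chrom", "bin1", "bin2", "count"])
        bias = estimate_bias(bp, CHROM)
        covered = bias.values["chrS1"][bias.values["chrS1"] > 0]
        assert np.allclose(covered, 1.0)

    def test_double_coverage_bin(self):
        bp = pd.DataFrame(
            [("chrS1", 0, 10, 2), ("chrS1", 1, 11, 1), ("chrS1", 2, 12, 1)],
            columns=["chrom", "bin1", "bin2", "count"],
        )
        bias = estimate_bias(bp, CHROM)
        v = bias.values["chrS1"]
        assert v[0] == pytest.approx(2 * v[1])

    def test_nonzero_bias_mean_is_one(self):
        cfg = SimConfig(seed=3)
        bp, _ = syn.sim_contacts(cfg, seed=3)
        bias = estimate_bias(bp, CHROM)
        assert bias.nonzero_mean == pytest.approx(1.0, abs=1e-6)

    def test_model_based_bias_flat_for_unbiased_data_even_at_edges(self):
        """With the decay model supplied, uniform-visibility data yields
        near-unit bias everywhere — including edge bins, whose raw coverage
        is depressed only because they have fewer candidate partners."""
        cfg = SimConfig(seed=5, bias_sd=0.0, n_planted_loops=0)
        bp, _ = syn.sim_contacts(cfg, seed=5)
        decay = fit_distance_decay(bp, CHROM)
        bias = estimate_bias(bp, CHROM, decay=decay)
        v = bias.values["chrS1"]
        assert v[v > 0].std() < 0.05
        assert v[0] == pytest.approx(1.0, abs=0.1)  # edge bin not penalized

    def test_model_based_bias_recovers_planted_visibility(self):
        """A bin with doubled visibility gets bias about 2."""
        cfg = SimConfig(seed=6, bias_sd=0.0, n_planted_loops=0)
        bp, _ = syn.sim_contacts(cfg, seed=6)
        hot = 200  # double every count involving bin 200
        m = (bp["bin1"] == hot) | (bp["bin2"] == hot)
        bp.loc[m, "count"] *= 2
        decay = fit_distance_decay(bp, CHROM)
        bias = estimate_bias(bp, CHROM, decay=decay)
        v = bias.values["chrS1"]
        assert v[hot] == pytest.approx(2.0, abs=0.25)


class TestCallLoops:
    def test_zero_count_never_significant(self):
        cfg = SimConfig(seed=4, n_planted_loops=0)
        bp, _ = syn.sim_contacts(cfg, seed=4)
        decay = fit_distance_decay(bp, CHROM)
        bias = estimate_bias(bp, CHROM)
        loops, cand = call_loops(bp, decay, bias, CHROM, return_candidates=True)
        zeros = cand[cand["count"] == 0]
        assert (zeros["p_value"] == 1.0).all()
        merged = zeros.merge(loops, left_on=["bin1"], right_on=loops["start1"] // 5_000)
        assert len(loops[loops["count"] == 0]) == 0

    def test_pvalues_match_exact_oracle(self):
        """Binomial tails agree with the direct log-pmf sum to 1e-10."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(100, 20_000))
            p = float(10 ** rng.uniform(-6, -2))
            k = int(rng.integers(0, 50))
            ours = float(stats.binom.sf(k - 1, n, p))
            assert ours == pytest.approx(binom_sf_oracle(k, n, p), abs=1e-10, rel=1e-9)
        # the documented reference point
        assert float(stats.binom.sf(9, 10_000, 1e-4)) == pytest.approx(
            binom_sf_oracle(10, 10_000, 1e-4), rel=1e-9
        )

    def test_emitted_loops_respect_distance_filter(self):
        cfg = SimConfig(seed=6)
        bp, _ = syn.sim_contacts(cfg, seed=6)
        res = HiChIPLoopModel(bp, CHROM).fit()
        assert (res.loops["distance"] >= 20_000).all()
        assert (res.loops["distance"] <= 2_000_000).all()

    def test_bad_fdr_rejected(self):
        cfg = SimConfig(seed=6)
        bp, _ = syn.sim_contacts(cfg, seed=6)
        decay = fit_distance_decay(bp, CHROM)
        bias = estimate_bias(bp, CHROM)
        with pytest.raises(ValueError):
            call_loops(bp, decay, bias, CHROM, fdr=0.0)


class TestMergeLoops:
    def test_self_merge_idempotent(self):
        loops = make_loops([("chr1", 0, 10), ("chr1", 5, 40)])
        merged = merge_loops([loops, loops])
        assert len(merged) == 2
        assert set(merged["source"]) == {"CL1"}

    def test_disjoint_union(self):
        a = make_loops([("chr1", 0, 10)])
        b = make_loops([("chr2", 0, 10)], source="CL2")
        assert len(merge_loops([a, b])) == 2

    def test_shared_loop_carries_both_sources_and_min_q(self):
        a = make_loops([("chr1", 0, 10)])
        b = make_loops([("chr1", 0, 10)], source="CL2")
        b.loc[0, "q_value"] = 1e-9
        merged = merge_loops([a, b])
        assert len(merged) == 1
        assert merged.iloc[0]["source"] == "CL1,CL2"
        assert merged.iloc[0]["q_value"] == 1e-9

    def test_mixed_resolutions_rejected(self):
        a = make_loops([("chr1", 0, 10)])
        b = make_loops([("chr1", 0, 10)])
        b["end1"] = b["start1"] + 10_000
        with pytest.raises(ValueError, match="resolution"):
            merge_loops([a, b])
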