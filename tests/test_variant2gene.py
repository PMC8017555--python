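"""Variant-to-gene assignment, open-chromatin filtering and set comparison."""

import numpy as np
import pandas as pd
import pytest

from loopgene.annotation import GeneModel, GenomeAnnotation
from loopgene.variant2gene import (
    compare_target_sets,
    filter_by_open_chromatin,
    load_published_locus_table,
    map_cvs_to_targets,
    proximal_targets,
    summarize_loci,
)
from conftest import make_loops


def _cvs(rows):
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "locus_id", "pp"])


def _gene(gid, start, end, strand="+", chrom="chr1"):
    return GeneModel(gene_id=gid, symbol=gid.upper(), chrom=chrom, strand=strand,
                     start=start, end=end, exons=((start, end),))


class TestMapCvsToTargets:
    def test_hand_computed_distance(self):
        """CV in one anchor links to the gene at the other; distance |pos-TSS|."""
        gene = _gene("g1", 302_000, 320_000)
        ann = GenomeAnnotation([gene])
        loops = make_loops([("chr1", 20, 60)])  # anchors [100k,105k) and [300k,305k)
        cvs = _cvs([("v1", "chr1", 102_501, "L1", 0.9)])  # 0-based 102_500
        links = map_cvs_to_targets(cvs, loops, ann)
        assert len(links) == 1
        assert links.iloc[0]["gene_id"] == "g1"
        assert links.iloc[0]["distance"] == 199_500

    def test_orientation_symmetry(self):
        """A CV in anchor2 maps to genes at anchor1."""
        gene = _gene("g1", 101_000, 110_000)
        ann = GenomeAnnotation([gene])
        loops = make_loops([("chr1", 20, 60)])
        cvs = _cvs([("v1", "chr1", 302_001, "L1", 0.9)])
        links = map_cvs_to_targets(cvs, loops, ann)
        assert links.iloc[0]["gene_id"] == "g1"

    def test_cv_outside_all_anchors(self):
        ann = GenomeAnnotation([_gene("g1", 302_000, 320_000)])
        loops = make_loops([("chr1", 20, 60)])
        links = map_cvs_to_targets(_cvs([("v1", "chr1", 700_001, "L1", 0.9)]), loops, ann)
        assert len(links) == 0

    def test_multiple_genes_at_target_anchor(self):
        genes = [_gene("g1", 300_500, 302_000), _gene("g2", 303_000, 304_000)]
        ann = GenomeAnnotation(genes)
        loops = make_loops([("chr1", 20, 60)])
        links = map_cvs_to_targets(_cvs([("v1", "chr1", 102_001, "L1", 0.9)]), loops, ann)
        assert sorted(links["gene_id"]) == ["g1", "g2"]

    def test_links_deduplicated(self):
        ann = GenomeAnnotation([_gene("g1", 302_000, 320_000)])
        loops = make_loops([("chr1", 20, 60)])
        cvs = _cvs([("v1", "chr1", 102_001, "L1", 0.9)] * 1)
        links = map_cvs_to_targets(pd.concat([cvs, cvs]), loops, ann)
        assert len(links) == 1


class TestOpenChromatinFilter:
    peaks_a = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200]})
    peaks_b = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [100, 500], "end": [200, 600]})

    def test_variant_in_all_sets_retained(self):
        t = _cvs([("v1", "chr1", 151, "L1", 0.5)])
        out = filter_by_open_chromatin(t, [self.peaks_a, self.peaks_b])
        assert list(out["variant_id"]) == ["v1"]

    def test_variant_in_one_set_removed_when_all_required(self):
        t = _cvs([("v1", "chr1", 551, "L1", 0.5)])
        assert len(filter_by_open_chromatin(t, [self.peaks_a, self.peaks_b])) == 0

    def test_any_mode_keeps_partial_hits(self):
        t = _cvs([("v1", "chr1", 551, "L1", 0.5)])
        out = filter_by_open_chromatin(t, [self.peaks_a, self.peaks_b], require_all=False)
        assert len(out) == 1

    def test_covering_set_is_identity(self):
        t = _cvs([("v1", "chr1", 151, "L1", 0.5), ("v2", "chr1", 191, "L1", 0.2)])
        cover = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000]})
        out = filter_by_open_chromatin(t, [cover], require_all=False)
        pd.testing.assert_frame_equal(out, t)

    def test_empty_peak_set_with_require_all_warns_and_empties(self, caplog):
        t = _cvs([("v1", "chr1", 151, "L1", 0.5)])
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        with caplog.at_level("WARNING"):
            out = filter_by_open_chromatin(t, [self.peaks_a, empty])
        assert len(out) == 0
        assert "empty peak set" in caplog.text

    def test_subset_and_monotonicity(self, rng):
        """Output is a subset of input; adding peaks never shrinks it."""
        t = _cvs([(f"v{i}", "chr1", int(p), "L1", 0.1)
                  for i, p in enumerate(rng.integers(1, 10_000, size=50))])
        starts = rng.integers(0, 10_000, size=5)
        peaks = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 500})
        more = pd.concat([peaks, pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10_000]})])
        out1 = filter_by_open_chromatin(t, [peaks])
        out2 = filter_by_open_chromatin(t, [more])
        assert set(out1["variant_id"]) <= set(t["variant_id"])
        assert set(out1["variant_id"]) <= set(out2["variant_id"])


class TestProximalTargets:
    genes = [_gene("g1", 1_000, 5_000), _gene("g2", 20_000, 30_000)]

    def test_containing_body_wins(self):
        ann = GenomeAnnotation(self.genes)
        out = proximal_targets(_cvs([("v1", "chr1", 2_001, "L1", 0.5)]), ann)
        assert out.iloc[0]["gene_id"] == "g1"
        assert out.iloc[0]["distance"] == 0

    def test_nearest_tss_otherwise(self):
        ann = GenomeAnnotation(self.genes)
        out = proximal_targets(_cvs([("v1", "chr1", 18_001, "L1", 0.5)]), ann)
        assert out.iloc[0]["gene_id"] == "g2"

    def test_equidistant_tie_goes_to_smaller_coordinate(self):
        genes = [_gene("gR", 20_000, 30_000), _gene("gL", 1_000, 10_000)]
        ann = GenomeAnnotation(genes)
        # TSSs at 1_000 and 20_000; 0-based midpoint 10_500 -> pos 10_501
        out = proximal_targets(_cvs([("v1", "chr1", 10_501, "L1", 0.5)]), ann)
        assert out.iloc[0]["gene_id"] == "gL"

    def test_gene_free_chromosome_omitted(self, caplog):
        ann = GenomeAnnotation(self.genes)
        with caplog.at_level("INFO"):
            out = proximal_targets(_cvs([("v1", "chr9", 100, "L1", 0.5)]), ann)
        assert len(out) == 0


class TestCompareTargetSets:
    def test_hand_computed(self):
        comp = compare_target_sets({"A", "B", "C"}, {"B"}, {"B", "C"})
        assert comp.overlap_hichip_eqtl == 1
        assert comp.overlap_hichip_proximal == 2
        assert comp.triple_overlap == 1
        assert comp.to_dict()["fold_vs_eqtl"] == 3.0
        assert comp.to_dict()["fold_vs_proximal"] == 1.5

    def test_identical_sets(self):
        s = {"A", "B"}
        comp = compare_target_sets(s, s, s)
        assert comp.triple_overlap == 2
        assert comp.to_dict()["fold_vs_eqtl"] == 1.0

    def test_disjoint_sets(self):
        comp = compare_target_sets({"A"}, {"B"}, {"C"})
        assert comp.overlap_hichip_eqtl == 0
        assert comp.triple_overlap == 0

    def test_empty_hichip_folds_unavailable(self):
        comp = compare_target_sets(set(), {"B"}, {"C"})
        assert comp.fold_vs_eqtl is None

    def test_case_normalization(self):
        comp = compare_target_sets({"myc"}, {"MYC"}, {"Myc"})
        assert comp.triple_overlap == 1

    def test_inclusion_exclusion_on_random_sets(self, rng):
        universe = [f"G{i}" for i in range(40)]
        for _ in range(25):
            h, e, p = (set(rng.choice(universe, size=rng.integers(1, 20), replace=False))
                       for _ in range(3))
            comp = compare_target_sets(h, e, p)
            union = len(h | e | p)
            by_ie = (
                comp.n_hichip + comp.n_eqtl + comp.n_proximal
                - comp.overlap_hichip_eqtl - comp.overlap_hichip_proximal
                - comp.overlap_eqtl_proximal + comp.triple_overlap
            )
            assert union == by_ie
            assert comp.triple_overlap <= min(
                comp.overlap_hichip_eqtl, comp.overlap_hichip_proximal,
                comp.overlap_eqtl_proximal,
            )


class TestSummarizeLoci:
    def test_published_cv_counts_sum_through_the_stage(self):
        """Feeding the published per-locus CV counts through the summary
        stage reproduces the published grand total of loop-linked CVs."""
        table = load_published_locus_table()
        rows = []
        for r in table.itertuples():
            genes = r.target_genes.split(",")
            for k in range(r.cv_count):
                rows.append(
                    {
                        "variant_id": f"{r.locus}_cv{k}",
                        "chrom": "chr1", "pos": 1 + k, "locus_id": r.locus,
                        "gene_id": genes[k % len(genes)], "loop_id": f"{r.locus}_loop",
                        "source": "SKOV3", "distance": 100_000, "anchor_distance": 100_000,
                    }
                )
        per_locus, totals = summarize_loci(pd.DataFrame(rows))
        assert len(per_locus) == 14
        assert per_locus["cv_count"].sum() == 649
        assert totals["total_cvs"] == 649

    def test_zero_links(self):
        per_locus, totals = summarize_loci(pd.DataFrame(
            columns=["variant_id", "locus_id", "gene_id", "source", "distance"]))
        assert len(per_locus) == 0
        assert totals["total_cvs"] == 0

    def test_shared_gene_counted_once_in_totals(self):
        links = pd.DataFrame(
            {
                "variant_id": ["v1", "v2"],
                "locus_id": ["L1", "L2"],
                "gene_id": ["gShared", "gShared"],
                "source": ["CL1", "CL1"],
                "distance": [50_000, 60_000],
            }
        )
        per_locus, totals = summarize_loci(links)
        assert totals["total_genes"] == 1
        assert per_locus["n_target_genes"].tolist() == [1, 1]

    def test_per_source_distance_statistics(self):
        links = pd.DataFrame(
            {
                "variant_id": ["v1", "v1", "v2"],
                "locus_id": ["L1", "L1", "L1"],
                "gene_id": ["g1", "g2", "g1"],
                "source": ["CL1", "CL1,CL2", "CL2"],
                "distance": [10_000, 20_000, 40_000],
            }
        )
        _, totals = summarize_loci(links)
        assert totals["per_source_median_distance"]["CL1"] == 15_000
        assert totals["per_source_median_distance"]["CL2"] == 30_000
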