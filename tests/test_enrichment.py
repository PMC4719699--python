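"""Annotation hierarchy, enrichment statistics vs oracles, proximity."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmrscan import (
    annotate_cpg_features,
    chisq_feature_enrichment,
    gwas_proximity,
    permutation_track_enrichment,
    tfbs_enrichment,
)
from dmrscan.dataio import AnnotationTrack


def _track(rows, name="t"):
    return AnnotationTrack(
        name,
        pd.DataFrame(rows, columns=["chromosome", "start", "end", "strand", "label"]),
    )


def _points(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "probe_id": [f"cg{i}" for i in range(len(positions))],
            "chromosome": chrom,
            "position": positions,
        }
    )


class TestAnnotation:
    GENES = [("chr1", 10_000, 20_000, "+", "gA"), ("chr1", 40_000, 50_000, "-", "gB")]
    ISLANDS = [("chr1", 14_000, 15_000, ".", "i1")]

    def annotate(self, positions):
        return annotate_cpg_features(
            _points(positions), _track(self.GENES, "genes"), _track(self.ISLANDS, "islands")
        )

    def test_upstream_of_plus_tss_is_promoter(self):
        # TSS of gA at 0-based 10,000; 1,500 bp upstream
        assert self.annotate([8_501]).iloc[0]["gene_label"] == "promoter"

    def test_minus_strand_tss_at_interval_end(self):
        # gB TSS at 0-based 49,999; 1,500 bp "upstream" = higher coordinate
        assert self.annotate([51_500]).iloc[0]["gene_label"] == "promoter"
        assert self.annotate([45_000]).iloc[0]["gene_label"] == "gene_body"

    def test_promoter_precedence_over_gene_body(self):
        # inside gA's body AND within 2 kb of gA's TSS
        assert self.annotate([11_000]).iloc[0]["gene_label"] == "promoter"

    def test_intergenic_far_from_genes(self):
        assert self.annotate([80_000]).iloc[0]["gene_label"] == "intergenic"

    def test_island_shore_shelf_sea_bands(self):
        labels = self.annotate([14_500, 13_500, 11_500, 9_000])["island_label"]
        assert list(labels) == ["island", "shore", "shelf", "sea"]

    def test_shelf_at_2500bp_from_island_edge(self):
        assert self.annotate([14_000 - 2_500]).iloc[0]["island_label"] == "shelf"

    def test_no_genes_everything_intergenic(self):
        empty = AnnotationTrack(
            "genes",
            pd.DataFrame(columns=["chromosome", "start", "end", "strand", "label"]),
        )
        ann = annotate_cpg_features(_points([100, 5000]), empty, _track(self.ISLANDS))
        assert (ann["gene_label"] == "intergenic").all()

    def test_gene_without_strand_is_error(self):
        genes = _track([("chr1", 100, 200, ".", "g")])
        with pytest.raises(ValueError, match="strand"):
            annotate_cpg_features(_points([150]), genes, _track(self.ISLANDS))

    def test_labels_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        ann = self.annotate(sorted(rng.choice(100_000, 200, replace=False) + 1))
        assert ann["gene_label"].isin(["promoter", "gene_body", "intergenic"]).all()
        assert ann["island_label"].isin(["island", "shore", "shelf", "sea"]).all()
        assert len(ann) == 200


def _chisq_oracle(a, b, c, d):
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def _fisher_oracle_greater(a, b, c, d):
    """One-sided hypergeometric tail by direct enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, row1)
    total = 0
    for k in range(a, min(row1, col1) + 1):
        if row1 - k > n - col1:
            continue
        total += comb(col1, k) * comb(n - col1, row1 - k)
    return total / denom


class TestChisq:
    def test_hand_computed_value(self):
        res = chisq_feature_enrichment(
            ["in"] * 50 + ["out"] * 50, ["in"] * 200 + ["out"] * 800, "in"
        )
        assert res.statistic == pytest.approx(46.5882352941, rel=1e-9)
        assert res.fold_enrichment == pytest.approx(2.5)

    def test_equal_proportions_give_zero(self):
        res = chisq_feature_enrichment(
            ["in", "out"], ["in"] * 10 + ["out"] * 10, "in"
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_degenerate_margin_flagged(self):
        res = chisq_feature_enrichment(["out"] * 5, ["out"] * 10, "in")
        assert res.degenerate and res.p == 1.0

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(250):
            a, b, c, d = rng.integers(1, 40, size=4)
            res = chisq_feature_enrichment(
                ["in"] * a + ["out"] * b, ["in"] * c + ["out"] * d, "in"
            )
            assert res.statistic == pytest.approx(_chisq_oracle(a, b, c, d), rel=1e-9)


class TestTfbs:
    def test_hand_enumerated_exact_p(self):
        # 2x2 table (3,1 / 1,3): one-sided p = (16 + 1)/70
        test_set = {"p1", "p2", "p3", "p4"}
        background = {"p1", "p2", "p3", "p4"}  # c,d built from motif map
        motif_map = pd.DataFrame(
            {"motif": ["m1"] * 1, "promoter": ["p1"]}
        )
        # direct scipy cross-check of the enumeration oracle itself
        assert _fisher_oracle_greater(3, 1, 1, 3) == pytest.approx(17 / 70)
        _, p = stats.fisher_exact([[3, 1], [1, 3]], alternative="greater")
        assert p == pytest.approx(17 / 70, rel=1e-10)

    def test_min_frac_filter_excludes_rare_motifs(self):
        test_set = {f"t{i}" for i in range(50)}
        background = test_set | {f"b{i}" for i in range(200)}
        rows = [("rare", "t0"), ("rare", "t1")]  # 4% of 50 -> excluded
        rows += [("common", p) for p in list(test_set)[:10]]
        results = tfbs_enrichment(test_set, background, pd.DataFrame(rows, columns=["motif", "promoter"]))
        labels = [r.label for r in results if not r.degenerate]
        assert "rare" not in labels and "common" in labels

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            tfbs_enrichment({"x"}, {"y"}, pd.DataFrame(columns=["motif", "promoter"]))

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(250):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            assert p == pytest.approx(_fisher_oracle_greater(a, b, c, d), rel=1e-9)

    def test_bonferroni_over_tested_motifs(self):
        test_set = {f"t{i}" for i in range(20)}
        background = test_set | {f"b{i}" for i in range(100)}
        rows = [("mA", p) for p in list(sorted(test_set))[:15]]
        rows += [("mB", p) for p in list(sorted(test_set))[:10]]
        results = tfbs_enrichment(
            test_set, background, pd.DataFrame(rows, columns=["motif", "promoter"])
        )
        tested = [r for r in results if not r.degenerate]
        for r in tested:
            assert r.p_corrected == pytest.approx(min(r.p * len(tested), 1.0))


class TestPermutation:
    DMRS = pd.DataFrame(
        {
            "chromosome": ["chr1"] * 5,
            "start": [1000, 5000, 9000, 13000, 17000],
            "end": [1500, 5500, 9500, 13500, 17500],
        }
    )
    LENGTHS = {"chr1": 1_000_000}

    def test_full_coverage_track_gives_p_one(self):
        track = _track([("chr1", 0, 1_000_000, ".", "all")])
        res = permutation_track_enrichment(self.DMRS, track, self.LENGTHS, n_perm=200, seed=0)
        assert res.a == 5 and res.p == pytest.approx(1.0)

    def test_empty_track_gives_zero_overlap_p_one(self):
        track = AnnotationTrack(
            "none", pd.DataFrame(columns=["chromosome", "start", "end", "strand", "label"])
        )
        res = permutation_track_enrichment(self.DMRS, track, self.LENGTHS, n_perm=200, seed=0)
        assert res.a == 0 and res.p == pytest.approx(1.0)

    def test_sparse_track_over_all_dmrs_is_significant(self):
        # track covers exactly the DMRs: ~0.25% of the chromosome
        track = _track(
            [("chr1", s - 1, e, ".", "x") for s, e in zip(self.DMRS["start"], self.DMRS["end"])]
        )
        res = permutation_track_enrichment(self.DMRS, track, self.LENGTHS, n_perm=2000, seed=1)
        assert res.a == 5
        assert res.p <= 0.01

    def test_reproducible_and_bounded(self):
        track = _track([("chr1", 0, 5000, ".", "x")])
        r1 = permutation_track_enrichment(self.DMRS, track, self.LENGTHS, n_perm=500, seed=3)
        r2 = permutation_track_enrichment(self.DMRS, track, self.LENGTHS, n_perm=500, seed=3)
        assert r1.p == r2.p
        assert 1 / 501 <= r1.p <= 1.0

    def test_dmr_longer_than_chromosome_rejected(self):
        dmrs = pd.DataFrame({"chromosome": ["chr1"], "start": [1], "end": [2_000_000]})
        track = _track([("chr1", 0, 5000, ".", "x")])
        with pytest.raises(ValueError, match="longer than chromosome"):
            permutation_track_enrichment(dmrs, track, self.LENGTHS, n_perm=10, seed=0)


class TestGwasProximity:
    DMRS = pd.DataFrame(
        {"chromosome": ["chr1", "chr1"], "start": [100_000, 500_000], "end": [101_000, 501_000]}
    )

    def _snps(self, rows):
        return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position", "pvalue"])

    def test_snp_inside_dmr_distance_zero_in_both_windows(self):
        snps = self._snps([("rs1", "chr1", 100_500, 1e-8)])
        out = gwas_proximity(self.DMRS, snps)
        assert out[2000].iloc[0]["distance"] == 0
        assert out[250_000].iloc[0]["distance"] == 0

    def test_boundary_inclusive_at_window_edge(self):
        snps = self._snps([("rs1", "chr1", 101_000 + 250_000, 1e-8)])
        out = gwas_proximity(self.DMRS, snps)
        first = out[250_000][out[250_000]["dmr_index"] == 0]
        assert len(first) == 1  # exactly 250 kb from the edge, inclusive
        assert first.iloc[0]["distance"] == 250_000
        assert len(out[2000]) == 0

    def test_weak_snp_filtered_entirely(self):
        snps = self._snps([("rs1", "chr1", 100_500, 1e-5)])
        out = gwas_proximity(self.DMRS, snps)
        assert len(out[2000]) == 0 and len(out[250_000]) == 0

    def test_100kb_snp_in_large_window_only(self):
        snps = self._snps([("rs1", "chr1", 201_000, 1e-8)])
        out = gwas_proximity(self.DMRS, snps)
        assert len(out[250_000]) == 1 and out[250_000].iloc[0]["distance"] == 100_000
        assert len(out[2000]) == 0
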