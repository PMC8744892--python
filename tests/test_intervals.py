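"""Interval algebra against brute-force oracles and rule boundaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ernascope.intervals import (
    GeneModel,
    GenomicInterval,
    annotate_nearest_expressed_gene,
    classify_location,
    intersect_sets,
    merge_intervals,
    overlap_bp,
    remove_blacklisted,
    reproducible_peaks,
    trim_to_center,
    window_around,
    windows_around,
)

from conftest import brute_shared_names, random_peaks


class TestOverlapBp:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 100, 200), ("chr1", 200, 300), 0),  # half-open adjacency
            (("chr1", 100, 200), ("chr1", 150, 250), 50),
            (("chr1", 100, 200), ("chr2", 100, 200), 0),
            (("chr1", 100, 200), ("chr1", 120, 130), 10),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_bp(GenomicInterval(*a), GenomicInterval(*b)) == expected

    def test_matches_per_base_oracle(self, rng):
        """Overlap equals counting shared integer base positions."""
        for _ in range(1000):
            c1, c2 = rng.choice(["chr1", "chr2"], 2)
            s1, s2 = rng.integers(0, 300, 2)
            a = GenomicInterval(c1, s1, s1 + int(rng.integers(1, 60)))
            b = GenomicInterval(c2, s2, s2 + int(rng.integers(1, 60)))
            bases_a = {(a.chrom, p) for p in range(a.start, a.end)}
            bases_b = {(b.chrom, p) for p in range(b.start, b.end)}
            assert overlap_bp(a, b) == len(bases_a & bases_b)

    @given(
        s1=st.integers(0, 10_000), l1=st.integers(1, 2_000),
        s2=st.integers(0, 10_000), l2=st.integers(1, 2_000),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_symmetric_bounded_and_halfopen(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        ov = overlap_bp(a, b)
        assert ov == overlap_bp(b, a)
        assert 0 <= ov <= min(l1, l2)
        # zero-length contact at a shared boundary never counts
        if s1 + l1 == s2 or s2 + l2 == s1:
            assert ov == 0

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)


class TestReproduciblePeaks:
    def test_identity_when_replicates_equal(self, rng):
        peaks = random_peaks(rng, 50)
        out = reproducible_peaks(peaks, peaks)
        assert len(out) == len(peaks)
        assert set(out["name"]) == set(peaks["name"])

    def test_single_bp_overlap_retained(self):
        rep1 = pd.DataFrame([{"chrom": "chr1", "start": 100, "end": 200,
                              "name": "a", "score": 0.0, "strand": "."}])
        rep2 = pd.DataFrame([{"chrom": "chr1", "start": 199, "end": 300,
                              "name": "b", "score": 0.0, "strand": "."}])
        assert len(reproducible_peaks(rep1, rep2)) == 1
        rep2_touching = rep2.assign(start=200)
        assert len(reproducible_peaks(rep1, rep2_touching)) == 0

    def test_matches_all_pairs_oracle(self, rng):
        rep1, rep2 = random_peaks(rng, 500), random_peaks(rng, 500)
        out = reproducible_peaks(rep1, rep2)
        assert set(out["name"]) == brute_shared_names(rep1, rep2, 1)

    def test_idempotent_against_own_output(self, rng):
        rep1, rep2 = random_peaks(rng, 200), random_peaks(rng, 200)
        out = reproducible_peaks(rep1, rep2)
        again = reproducible_peaks(out, out)
        pd.testing.assert_frame_equal(out.reset_index(drop=True), again)


class TestBlacklist:
    def test_empty_blacklist_is_identity(self, rng):
        peaks = random_peaks(rng, 30)
        out = remove_blacklisted(peaks, peaks.iloc[0:0])
        pd.testing.assert_frame_equal(out, peaks)

    def test_contained_peak_dropped(self):
        peak = pd.DataFrame([{"chrom": "chr1", "start": 150, "end": 160,
                              "name": "p", "score": 0.0, "strand": "."}])
        bl = pd.DataFrame([{"chrom": "chr1", "start": 100, "end": 200}])
        assert len(remove_blacklisted(peak, bl)) == 0

    def test_matches_all_pairs_oracle(self, rng):
        peaks, bl = random_peaks(rng, 300), random_peaks(rng, 100)
        bl["name"] = [f"b{i}" for i in range(len(bl))]
        out = remove_blacklisted(peaks, bl)
        expected = set(peaks["name"]) - brute_shared_names(peaks, bl, 1)
        assert set(out["name"]) == expected


class TestWindows:
    def test_center_arithmetic(self):
        win = window_around(GenomicInterval("chr1", 1000, 1200), 588)
        assert (win.start, win.end) == (806, 1394)  # center 1100, +-294

    def test_clipping_at_chromosome_start(self):
        win = window_around(GenomicInterval("chr1", 10, 110), 1000)
        assert win.start == 0
        assert win.length < 1000

    def test_identity_width(self):
        peak = GenomicInterval("chr1", 500, 700)
        win = window_around(peak, 200)
        assert (win.start, win.end) == (peak.start, peak.end)

    def test_trim_to_center_default(self):
        win = trim_to_center(GenomicInterval("chr1", 1000, 1200))
        assert (win.start, win.end) == (1050, 1150)

    def test_vectorised_matches_scalar(self, rng):
        peaks = random_peaks(rng, 100)
        vec = windows_around(peaks, 588)
        for i in peaks.index:
            win = window_around(
                GenomicInterval(peaks.loc[i, "chrom"], int(peaks.loc[i, "start"]),
                                int(peaks.loc[i, "end"])), 588)
            assert (vec.loc[i, "start"], vec.loc[i, "end"]) == (win.start, win.end)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            window_around(GenomicInterval("chr1", 0, 10), 0)


class TestIntersectSets:
    def test_disjoint(self, rng):
        a = random_peaks(rng, 20, chroms=("chr1",))
        b = a.copy()
        b["chrom"] = "chr9"
        rep = intersect_sets(a, b, 1)
        assert (rep.a_only, rep.b_only, rep.shared_a, rep.shared_b) == (20, 20, 0, 0)

    def test_threshold_boundary_at_10bp(self):
        a = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100}])
        b9 = pd.DataFrame([{"chrom": "chr1", "start": 91, "end": 200}])
        b10 = pd.DataFrame([{"chrom": "chr1", "start": 90, "end": 200}])
        assert intersect_sets(a, b9, 10).shared_a == 0
        assert intersect_sets(a, b10, 10).shared_a == 1

    @pytest.mark.parametrize("min_bp", [1, 10])
    def test_matches_all_pairs_oracle(self, rng, min_bp):
        a, b = random_peaks(rng, 300), random_peaks(rng, 300)
        rep = intersect_sets(a, b, min_bp)
        assert rep.shared_a == len(brute_shared_names(a, b, min_bp))
        assert rep.shared_b == len(brute_shared_names(b, a, min_bp))
        assert rep.a_only + rep.shared_a == len(a)
        assert rep.b_only + rep.shared_b == len(b)

    def test_symmetry_on_swap(self, rng):
        a, b = random_peaks(rng, 150), random_peaks(rng, 150)
        fwd, rev = intersect_sets(a, b, 10), intersect_sets(b, a, 10)
        assert (fwd.a_only, fwd.shared_a) == (rev.b_only, rev.shared_b)


class TestMerge:
    def test_bookended_joined(self):
        df = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 50], "end": [100, 150]})
        out = merge_intervals(df)
        assert out.to_records(index=False).tolist() == [("chr1", 0, 150)]
        touching = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 150]})
        assert len(merge_intervals(touching)) == 1

    def test_matches_per_base_oracle(self, rng):
        df = random_peaks(rng, 200, max_pos=5000)
        out = merge_intervals(df)
        covered = set()
        for _, r in df.iterrows():
            covered.update((r["chrom"], p) for p in range(r["start"], r["end"]))
        merged_cover = set()
        for _, r in out.iterrows():
            merged_cover.update((r["chrom"], p) for p in range(r["start"], r["end"]))
        assert merged_cover == covered
        # intervals are disjoint and non-bookended after merging
        for chrom, sub in out.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()


def _toy_genes():
    """Two expressed genes on chr1 with TSSs at 11000 (+) and 51000 (-)."""
    g1 = GeneModel(
        "geneA",
        GenomicInterval("chr1", 10_000, 16_000, "+"),
        [11_000],
        [
            ("promoter", GenomicInterval("chr1", 10_000, 12_000, "+")),
            ("exon", GenomicInterval("chr1", 11_000, 11_500, "+")),
            ("intron", GenomicInterval("chr1", 11_500, 15_000, "+")),
            ("exon", GenomicInterval("chr1", 15_000, 15_500, "+")),
            ("three_prime_utr", GenomicInterval("chr1", 15_500, 16_000, "+")),
        ],
        expressed=True,
    )
    g2 = GeneModel(
        "geneB",
        GenomicInterval("chr1", 45_000, 52_000, "-"),
        [51_000],
        [
            ("promoter", GenomicInterval("chr1", 50_000, 52_000, "-")),
            ("exon", GenomicInterval("chr1", 45_000, 51_000, "-")),
        ],
        expressed=True,
    )
    return [g1, g2]


class TestClassifyLocation:
    def test_tss_distance_rule_boundary(self):
        genes = _toy_genes()
        # center 999 bp left of the geneA TSS: within 1 kb -> not intergenic
        near = GenomicInterval("chr1", 9_951, 10_051)
        assert classify_location(near, genes) != "intergenic"
        # center 1001 bp past: promoter feature also out of reach -> intergenic
        far = GenomicInterval("chr1", 20_000, 20_100)
        assert classify_location(far, genes) == "intergenic"

    def test_feature_precedence(self):
        genes = _toy_genes()
        over_exon = GenomicInterval("chr1", 15_100, 15_200)
        assert classify_location(over_exon, genes) == "exon"
        over_intron = GenomicInterval("chr1", 13_000, 13_100)
        assert classify_location(over_intron, genes) == "intron"
        over_utr = GenomicInterval("chr1", 15_600, 15_700)
        assert classify_location(over_utr, genes) == "UTR"

    def test_matches_literal_rule_oracle(self, rng):
        genes = _toy_genes()
        for _ in range(300):
            s = int(rng.integers(0, 60_000))
            peak = GenomicInterval("chr1", s, s + int(rng.integers(50, 400)))
            got = classify_location(peak, genes)
            # oracle: literal application of the stated rule
            hits = set()
            near = False
            for g in genes:
                for pos in g.tss:
                    if abs(peak.center - pos) <= 1000:
                        near = True
                for kind, iv in g.features:
                    if overlap_bp(peak, iv) > 0:
                        hits.add("UTR" if "utr" in kind else kind)
            if not hits and not near:
                assert got == "intergenic"
            else:
                assert got != "intergenic"
                for kind in ("promoter", "exon", "UTR", "intron"):
                    if kind in hits:
                        assert got == kind
                        break


class TestNearestGene:
    def test_peak_on_tss(self):
        ann = annotate_nearest_expressed_gene(
            pd.DataFrame([{"chrom": "chr1", "start": 10_950, "end": 11_050}]),
            _toy_genes(),
        )
        assert ann.loc[0, "nearest_gene"] == "geneA"
        assert ann.loc[0, "distance_to_tss"] == 0

    def test_equidistant_tie_breaks_lexicographically(self):
        genes = _toy_genes()
        # TSSs at 11000 and 51000; center 31000 is equidistant
        ann = annotate_nearest_expressed_gene(
            pd.DataFrame([{"chrom": "chr1", "start": 30_950, "end": 31_050}]), genes
        )
        assert ann.loc[0, "nearest_gene"] == "geneA"

    def test_sign_follows_gene_strand(self):
        genes = _toy_genes()
        ann = annotate_nearest_expressed_gene(
            pd.DataFrame([{"chrom": "chr1", "start": 8_950, "end": 9_050}]), genes
        )
        # peak upstream of the + strand TSS -> negative distance
        assert ann.loc[0, "distance_to_tss"] == -2000

    def test_unexpressed_genes_ignored(self):
        genes = _toy_genes()
        genes[0].expressed = False
        ann = annotate_nearest_expressed_gene(
            pd.DataFrame([{"chrom": "chr1", "start": 10_950, "end": 11_050}]), genes
        )
        assert ann.loc[0, "nearest_gene"] == "geneB"

    def test_matches_min_distance_oracle(self, rng):
        genes = _toy_genes()
        peaks = random_peaks(rng, 200, chroms=("chr1",), max_pos=60_000)
        ann = annotate_nearest_expressed_gene(peaks, genes)
        for i in peaks.index:
            center = (peaks.loc[i, "start"] + peaks.loc[i, "end"]) // 2
            best = min(
                ((abs(center - pos), g.gene_id) for g in genes for pos in g.tss),
            )
            assert ann.loc[i, "nearest_gene"] == best[1]

    def test_intergenic_calls_agree_with_distance(self, rng):
        genes = _toy_genes()
        peaks = random_peaks(rng, 200, chroms=("chr1",), max_pos=60_000)
        ann = annotate_nearest_expressed_gene(peaks, genes)
        inter = ann[ann["location_class"] == "intergenic"]
        assert (inter["distance_to_tss"].abs() > 1000).all()
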