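"""Peak annotation, presence classes, primed chromatin, and TE-overlap nulls."""

import numpy as np
import pytest

import ervatac as ev


def gene(tid="t1", tss=5000, strand="+", exons=None, chrom="chr1"):
    if exons is None:
        exons = ((5000, 5500), (6000, 7000)) if strand == "+" else \
                ((3000, 4000), (4500, 5001))
    return ev.TranscriptModel(tid, tid, chrom, strand, tuple(exons))


def peak(center, half=50, chrom="chr1"):
    return ev.GenomicInterval(chrom, center - half, center + half)


class TestAnnotatePeakFeature:
    def test_upstream_center_is_promoter(self):
        ann = ev.annotate_peak_feature(peak(4500), [gene()])
        assert ann.category == "promoter" and ann.nearest_gene == "t1"
        assert ann.distance_to_tss == -500

    def test_promoter_window_end_exclusive_gives_exon(self):
        ann = ev.annotate_peak_feature(peak(5100), [gene()])
        assert ann.category == "exon"

    def test_gene_free_chromosome_is_intergenic(self):
        ann = ev.annotate_peak_feature(peak(5000, chrom="chr2"), [gene()])
        assert ann.category == "intergenic" and ann.nearest_gene is None

    def test_intron_and_tts_and_minus_strand_mirror(self):
        g = gene()
        assert ev.annotate_peak_feature(peak(5800), [g]).category == "intron"
        assert ev.annotate_peak_feature(peak(7500), [g]).category == "TTS"
        gm = gene(tid="tm", tss=5000, strand="-")
        # 500 bp upstream on '-' is to the right of the TSS
        assert ev.annotate_peak_feature(peak(5500), [gm]).category == "promoter"
        assert ev.annotate_peak_feature(peak(5500), [gm]).distance_to_tss == -500

    def test_promoter_priority_over_exon(self):
        # center inside exon 1 of one gene and promoter of another
        g1 = gene(tid="a", tss=5000)
        g2 = gene(tid="b", tss=5300, exons=((5300, 5600),))
        assert ev.annotate_peak_feature(peak(5250), [g1, g2]).category == "promoter"


class TestProximalDistal:
    def test_boundary_inclusive(self):
        peaks = ev.IntervalSet([peak(1000), peak(2001), peak(9000)])
        prox, dist = ev.split_proximal_distal(peaks, [("chr1", 2000)], radius=1000)
        assert [p.center for p in prox] == [1000, 2001]
        assert [p.center for p in dist] == [9000]
        assert len(prox) + len(dist) == 3

    def test_no_tss_all_distal(self):
        peaks = ev.IntervalSet([peak(1000)])
        prox, dist = ev.split_proximal_distal(peaks, [])
        assert len(prox) == 0 and len(dist) == 1


class TestPresenceClasses:
    def stage_sets(self, patterns, layout):
        """Build 3-stage peak sets from explicit per-region patterns."""
        regions = [ev.GenomicInterval("chr1", 1000 * i, 1000 * i + 500)
                   for i in range(len(patterns))]
        stages = ["E18O", "P1O", "NGO"]
        peaks = {st: ev.IntervalSet([r for r, p in zip(regions, patterns) if p[j]],
                                    layout=layout)
                 for j, st in enumerate(stages)}
        return ev.StagePeakSets(stages=stages, peaks=peaks)

    def test_anchored_class_numbers(self, layout):
        s = self.stage_sets([(False, True, True), (False, False, True),
                             (True, True, True)], layout)
        pm = ev.presence_classes(s)
        assert pm.classes == [3, 4, 5]

    def test_all_seven_patterns_distinct(self, layout):
        patterns = [p for p in
                    [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
                    if any(p)]
        s = self.stage_sets(patterns, layout)
        pm = ev.presence_classes(s)
        assert sorted(pm.classes) == [1, 2, 3, 4, 5, 6, 7]
        assert len(pm.classes) == len(pm.universe)

    def test_class_counts_sum_to_universe(self, small_data):
        pm = ev.presence_classes(small_data["peaks"])
        assert len(pm.classes) == len(pm.universe)
        assert set(pm.classes) <= set(range(1, 8))

    def test_non_three_stage_input_gets_bitstrings(self, layout):
        regions = [ev.GenomicInterval("chr1", 0, 500)]
        peaks = {"a": ev.IntervalSet(regions, layout=layout),
                 "b": ev.IntervalSet([], layout=layout)}
        pm = ev.presence_classes(ev.StagePeakSets(stages=["a", "b"], peaks=peaks))
        assert pm.classes == ["+-"]


class TestPrimedPeaks:
    def test_overlap_keeps_ngo_coordinates(self, layout):
        ngo = ev.IntervalSet([ev.GenomicInterval("chr1", 100, 200)], layout=layout)
        go = ev.IntervalSet([ev.GenomicInterval("chr1", 150, 250)], layout=layout)
        out = ev.primed_peaks(ngo, go)
        assert [(p.start, p.end) for p in out] == [(100, 200)]

    def test_disjoint_sets_empty_and_subset_property(self, layout):
        rng = np.random.default_rng(8)
        from conftest import random_interval_set
        ngo = random_interval_set(rng, layout, 50)
        go = random_interval_set(rng, layout, 50)
        out = ev.primed_peaks(ngo, go)
        ngo_keys = {(p.chrom, p.start, p.end) for p in ngo}
        assert all((p.chrom, p.start, p.end) in ngo_keys for p in out)
        empty = ev.IntervalSet([], layout=layout)
        assert len(ev.primed_peaks(ngo, empty)) == 0
        # NGO peaks fully contained in GO peaks are always returned
        contained = ev.IntervalSet([ev.GenomicInterval("chr1", 10, 20)], layout=layout)
        cover = ev.IntervalSet([ev.GenomicInterval("chr1", 0, 100)], layout=layout)
        assert len(ev.primed_peaks(contained, cover)) == 1


class TestNearestDistalDistance:
    def test_example_and_empty(self, layout):
        distal = ev.IntervalSet([peak(8500), peak(12_000)], layout=layout)
        assert ev.nearest_distal_distance(("chr1", 10_000), distal) == 1500
        assert ev.nearest_distal_distance(("chr1", 1), ev.IntervalSet([])) is None

    def test_matches_all_pairs_scan(self, layout):
        rng = np.random.default_rng(12)
        from conftest import random_interval_set
        distal = random_interval_set(rng, layout, 60)
        tss = [(layout.chromosomes[int(rng.integers(2))], int(rng.integers(0, 50_000)))
               for _ in range(40)]
        fast = ev.nearest_distal_distances(tss, distal)
        for (chrom, pos), d in zip(tss, fast):
            centers = [p.center for p in distal if p.chrom == chrom]
            expect = min((abs(pos - c) for c in centers), default=None)
            assert d == expect


class TestExpectedTeOverlap:
    def test_full_coverage_gives_one(self, layout):
        te = ev.IntervalSet([ev.GenomicInterval(c, 0, layout.length(c))
                             for c in layout.chromosomes], layout=layout).merge()
        peaks = ev.IntervalSet([peak(1000), peak(5000)], layout=layout)
        r = ev.expected_te_overlap(peaks, te, layout)
        assert r["observed"] == 1.0 and r["expected_analytic"] == 1.0

    def test_uniform_peaks_match_analytic_within_3se(self, layout):
        te = ev.IntervalSet([ev.GenomicInterval("chr1", 0, 40_000),
                             ev.GenomicInterval("chr2", 0, 20_000)],
                            layout=layout).merge()  # 40% of 150 kb
        rng = np.random.default_rng(15)
        n = 10_000
        ivs = []
        for _ in range(n):
            chrom = "chr1" if rng.random() < 100 / 150 else "chr2"
            s = int(rng.integers(0, layout.length(chrom) - 1))
            ivs.append(ev.GenomicInterval(chrom, s, s + 1))
        peaks = ev.IntervalSet(ivs, layout=layout)
        r = ev.expected_te_overlap(peaks, te, layout)
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(r["observed"] - 0.4) < 3 * se

    def test_shuffle_null_consistent_with_analytic(self, layout):
        rng = np.random.default_rng(16)
        from conftest import random_interval_set
        te = random_interval_set(rng, layout, 80, max_len=800).merge()
        peaks = random_interval_set(rng, layout, 300, max_len=300)
        r = ev.expected_te_overlap(peaks, te, layout, mode="shuffle",
                                   n_shuffles=200, seed=1)
        assert abs(r["expected_shuffle"] - r["expected_analytic"]) < \
            3 * r["shuffle_se"] + 1e-9

    def test_shuffle_mode_needs_shuffles(self, layout):
        peaks = ev.IntervalSet([peak(1000)], layout=layout)
        te = peaks.merge()
        with pytest.raises(ValueError):
            ev.expected_te_overlap(peaks, te, layout, mode="shuffle", n_shuffles=0)


class TestSignalOverRegions:
    def test_single_fragment_single_bin(self):
        frags = ev.IntervalSet([ev.GenomicInterval("chr1", 100, 200)])
        regions = ev.IntervalSet([ev.GenomicInterval("chr1", 0, 1000)])
        mat = ev.signal_over_regions(frags, regions, flank_bp=0, n_bins=10)
        assert mat.shape == (1, 10)
        assert mat[0, 1] == 1 and mat.sum() == 1

    def test_scale_linearity_and_strand_reversal(self):
        frags = ev.IntervalSet([ev.GenomicInterval("chr1", 0, 100)])
        plus = ev.IntervalSet([ev.GenomicInterval("chr1", 0, 1000, "+")])
        minus = ev.IntervalSet([ev.GenomicInterval("chr1", 0, 1000, "-")])
        m1 = ev.signal_over_regions(frags, plus, n_bins=10)
        m2 = ev.signal_over_regions(frags, plus, n_bins=10, scale=2.0)
        assert np.array_equal(m2, 2 * m1)
        m3 = ev.signal_over_regions(frags, minus, n_bins=10)
        assert np.array_equal(m3[0], m1[0][::-1])

    def test_uniform_fragments_give_flat_profile(self, layout):
        rng = np.random.default_rng(17)
        ivs = []
        for _ in range(20_000):
            s = int(rng.integers(0, layout.length("chr1") - 50))
            ivs.append(ev.GenomicInterval("chr1", s, s + 50))
        frags = ev.IntervalSet(ivs, layout=layout)
        regions = ev.IntervalSet([ev.GenomicInterval("chr1", 40_000, 50_000)])
        prof = ev.signal_over_regions(frags, regions, n_bins=10)[0]
        assert prof.std() / prof.mean() < 0.1
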