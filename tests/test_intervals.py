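"""Interval algebra and flat-file parser tests, including brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

import ervatac as ev
from conftest import brute_force_covered, brute_force_intersect, random_interval_set


class TestBedParsing:
    def test_bed3_and_bed6(self, tmp_path, layout):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\nchr1\t100\t200\tp1\t0\t-\n")
        s = ev.read_bed(p, layout)
        assert (s.intervals[0].start, s.intervals[0].end, s.intervals[0].strand) == (100, 200, ".")
        assert s.intervals[1].strand == "-" and s.intervals[1].name == "p1"

    @pytest.mark.parametrize("line,msg", [
        ("chr1\t200\t100", "start >= end"),
        ("chr1\t100", "columns"),
        ("chr1\tx\t200", "coordinates"),
    ])
    def test_malformed_lines_raise_with_line_number(self, tmp_path, layout, line, msg):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(ev.ParseError, match="2"):
            ev.read_bed(p, layout)

    def test_interval_outside_layout_names_record(self, tmp_path, layout):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t200000\n")
        with pytest.raises(ev.ValidationError, match="chr1"):
            ev.read_bed(p, layout)

    def test_round_trip_preserves_coordinates_and_strand(self, tmp_path, layout):
        rng = np.random.default_rng(3)
        s = random_interval_set(rng, layout, 50, stranded=True)
        p = tmp_path / "rt.bed"
        ev.write_bed(s, p)
        back = ev.read_bed(p, layout)
        orig = sorted((i.chrom, i.start, i.end, i.strand) for i in s)
        got = sorted((i.chrom, i.start, i.end, i.strand) for i in back)
        assert got == orig


class TestGtfParsing:
    def test_one_based_conversion_and_intron(self, tmp_path, layout):
        p = tmp_path / "x.gtf"
        p.write_text(
            'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\t.\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n')
        (t,) = ev.read_gtf(p, layout)
        assert t.exons == ((100, 200), (300, 400))
        assert ev.intron_chain(t) == [(200, 300)]

    def test_missing_transcript_id(self, tmp_path, layout):
        p = tmp_path / "x.gtf"
        p.write_text('chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "g1";\n')
        with pytest.raises(ev.ParseError, match="transcript_id"):
            ev.read_gtf(p, layout)

    def test_mixed_strands_rejected(self, tmp_path, layout):
        p = tmp_path / "x.gtf"
        p.write_text(
            'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\t.\texon\t301\t400\t.\t-\t.\tgene_id "g1"; transcript_id "t1";\n')
        with pytest.raises(ev.ValidationError, match="strand"):
            ev.read_gtf(p, layout)

    def test_writer_round_trip(self, tmp_path, layout, small_data):
        p = tmp_path / "rt.gtf"
        subset = small_data["assembled"][:40]
        ev.write_gtf(subset, p)
        big = ev.GenomeLayout({c: 10_000_000 for c in ["chr1", "chr2"]})
        back = ev.read_gtf(p, big)
        assert {(t.transcript_id, t.exons) for t in back} == \
               {(t.transcript_id, t.exons) for t in subset}


class TestRepeatMaskerParsing:
    HEADER = "h1\nh2\n\n"

    def test_body_line(self, tmp_path, layout):
        p = tmp_path / "x.out"
        p.write_text(self.HEADER +
                     "1200 1.0 0.1 0.2 chr1 501 700 (0) + RLTR10 LTR/ERVK 1 200 (0) 1\n"
                     "800 1.0 0.1 0.2 chr1 901 950 (0) C B1_Mm SINE/B1 1 50 (0) 2\n")
        a, b = ev.read_repeatmasker_out(p, layout)
        assert (a.interval.start, a.interval.end, a.interval.strand) == (500, 700, "+")
        assert (a.type, a.te_class, a.family, a.sw_score) == ("RLTR10", "LTR", "ERVK", 1200)
        assert b.interval.strand == "-" and b.family == "B1"

    def test_non_numeric_score(self, tmp_path, layout):
        p = tmp_path / "x.out"
        p.write_text(self.HEADER + "xx 1 1 1 chr1 501 700 (0) + R L/T 1 2 (0) 1\n")
        with pytest.raises(ev.ParseError, match="SW"):
            ev.read_repeatmasker_out(p, layout)

    def test_round_trip_count_and_coords(self, tmp_path, small_data):
        p = tmp_path / "rt.out"
        ev.write_repeatmasker_out(small_data["te"], p)
        back = ev.read_repeatmasker_out(p, small_data["layout"])
        assert len(back) == len(small_data["te"])
        assert {(c.interval.chrom, c.interval.start, c.interval.end,
                 c.interval.strand, c.type, c.sw_score) for c in back} == \
               {(c.interval.chrom, c.interval.start, c.interval.end,
                 c.interval.strand, c.type, c.sw_score) for c in small_data["te"]}


class TestAlgebra:
    def test_intersect_examples(self, layout):
        a = ev.IntervalSet([ev.GenomicInterval("chr1", 0, 10, "+")], layout=layout)
        b = ev.IntervalSet([ev.GenomicInterval("chr1", 5, 20, "-")], layout=layout)
        pairs = ev.intersect(a, b)
        assert len(pairs) == 1 and pairs[0][2] == 5
        assert ev.intersect(a, b, same_strand=True) == []

    def test_intersect_matches_brute_force(self, layout):
        rng = np.random.default_rng(7)
        for _ in range(30):
            a = random_interval_set(rng, layout, int(rng.integers(5, 40)), stranded=True)
            b = random_interval_set(rng, layout, int(rng.integers(5, 40)), stranded=True)
            for same in (False, True):
                got = {(id(x), id(y), ov) for x, y, ov in ev.intersect(a, b, same)}
                exp = {(id(x), id(y), ov) for x, y, ov in brute_force_intersect(a, b, same)}
                assert got == exp

    def test_covered_bp_examples(self, layout):
        s = ev.IntervalSet([ev.GenomicInterval("chr1", 940, 1012)], layout=layout).merge()
        assert s.covered_bp(ev.GenomicInterval("chr1", 950, 1050)) == 62
        empty = ev.IntervalSet([], layout=layout).merge()
        assert empty.covered_bp(ev.GenomicInterval("chr1", 0, 100)) == 0
        tiling = ev.IntervalSet([ev.GenomicInterval("chr1", 0, 50),
                                 ev.GenomicInterval("chr1", 50, 100)], layout=layout).merge()
        assert tiling.covered_bp(ev.GenomicInterval("chr1", 0, 100)) == 100

    def test_merge_bookended_and_idempotent(self, layout):
        s = ev.IntervalSet([ev.GenomicInterval("chr1", 0, 10),
                            ev.GenomicInterval("chr1", 5, 20)], layout=layout)
        m = s.merge()
        assert [(i.start, i.end) for i in m] == [(0, 20)]
        assert ev.IntervalSet([], layout=layout).merge().intervals == []
        rng = np.random.default_rng(5)
        s = random_interval_set(rng, layout, 200)
        m = s.merge()
        m2 = m.merge()
        assert [(i.chrom, i.start, i.end) for i in m] == \
               [(i.chrom, i.start, i.end) for i in m2]
        # covered bp equals the per-base oracle on each chromosome
        for chrom in layout.chromosomes:
            q = ev.GenomicInterval(chrom, 0, layout.length(chrom))
            assert m.covered_bp(q) == brute_force_covered(q, s.intervals)

    def test_shuffle_contracts(self, layout):
        tiny = ev.GenomeLayout({"chrA": 10})
        s = ev.IntervalSet([ev.GenomicInterval("chrA", 0, 10)], layout=tiny)
        out = ev.shuffle_intervals(s, tiny, seed=1)
        assert (out.intervals[0].start, out.intervals[0].end) == (0, 10)

        rng = np.random.default_rng(9)
        s = random_interval_set(rng, layout, 100)
        a = ev.shuffle_intervals(s, layout, seed=42)
        b = ev.shuffle_intervals(s, layout, seed=42)
        assert [(i.chrom, i.start) for i in a] == [(i.chrom, i.start) for i in b]
        assert sorted(i.length for i in a) == sorted(i.length for i in s)

    def test_shuffle_start_uniformity(self):
        """Chi-squared goodness of fit of shuffled 1 bp starts at alpha=0.01."""
        L = 20
        lay = ev.GenomeLayout({"c": L})
        s = ev.IntervalSet([ev.GenomicInterval("c", 0, 1)], layout=lay)
        starts = [ev.shuffle_intervals(s, lay, seed=1000 + i).intervals[0].start
                  for i in range(10_000)]
        counts = np.bincount(starts, minlength=L)
        chi2 = ((counts - len(starts) / L) ** 2 / (len(starts) / L)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=L - 1)
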