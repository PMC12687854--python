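"""Binomial observed/expected enrichment and neighbor-gene statistics."""

import math

import numpy as np
import pytest
from scipy import stats

import ervatac as ev
from conftest import random_interval_set


def exact_binomial_tail(observed, n, p):
    """Independent oracle: direct summation of the binomial pmf."""
    return sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k)
               for k in range(observed, n + 1))


class TestBinomialTail:
    def test_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(1, 51))
            obs = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            assert ev.binomial_tail(obs, n, p) == \
                pytest.approx(exact_binomial_tail(obs, n, p), abs=1e-12)

    def test_edge_cases(self):
        assert ev.binomial_tail(0, 10, 0.3) == 1.0
        assert ev.binomial_tail(10, 10, 0.3) == pytest.approx(0.3 ** 10, rel=1e-12)


class TestBinomialEnrichment:
    def test_worked_example(self):
        r = ev.binomial_enrichment(30, 100, 0.1)
        assert r.expected_reads == pytest.approx(10.0)
        assert r.fold == pytest.approx(3.0)
        assert r.p_value < 1e-6 and r.enriched

    def test_zero_observed(self):
        r = ev.binomial_enrichment(0, 100, 0.1)
        assert r.fold == 0.0 and r.p_value == 1.0 and not r.enriched

    def test_fold_gate_blocks_low_fold_calls(self):
        # every fragment in the type, but prevalence so high that fold ~ 1
        r = ev.binomial_enrichment(100, 100, 0.999)
        assert r.p_value < 1.0 and r.fold < 2.0 and not r.enriched

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            ev.binomial_enrichment(1, 10, 0.0)


class TestReadsPerErvType:
    def build(self, rng, layout, n_te=30, n_peaks=15, n_frags=200):
        types = ["RLTR10", "MTA_Mm", "IAP"]
        te = []
        for i in range(n_te):
            chrom = layout.chromosomes[int(rng.integers(2))]
            s = int(rng.integers(0, layout.length(chrom) - 400))
            te.append(ev.TECopy(
                ev.GenomicInterval(chrom, s, s + int(rng.integers(50, 400))),
                types[i % 3], "LTR", "ERVK", int(rng.integers(100, 9000))))
        peaks = random_interval_set(rng, layout, n_peaks, max_len=2000)
        frags = random_interval_set(rng, layout, n_frags, max_len=100)
        return te, peaks, frags

    def oracle(self, fragments, peaks_merged, te):
        """Brute-force triple loop over fragments x peaks x copies."""
        counts, n_total = {}, 0
        for f in fragments:
            c = f.center
            if not any(p.chrom == f.chrom and p.start <= c < p.end
                       for p in peaks_merged):
                continue
            n_total += 1
            covering = [t for t in te if t.interval.chrom == f.chrom
                        and t.interval.start <= c < t.interval.end]
            if covering:
                best = max(covering, key=lambda t: t.sw_score)
                counts[best.type] = counts.get(best.type, 0) + 1
        return counts, n_total

    def test_matches_brute_force_oracle(self, layout):
        rng = np.random.default_rng(21)
        for _ in range(20):
            te, peaks, frags = self.build(rng, layout)
            got, n_total = ev.reads_per_erv_type(frags, peaks, te)
            exp, n_exp = self.oracle(frags, peaks.merge(), te)
            assert n_total == n_exp
            assert {t: c for t, c in got.items() if c} == exp
            assert sum(got.values()) <= n_total

    def test_fragment_outside_peaks_not_counted(self, layout):
        te = [ev.TECopy(ev.GenomicInterval("chr1", 0, 1000), "RLTR10", "LTR",
                        "ERVK", 5000)]
        peaks = ev.IntervalSet([ev.GenomicInterval("chr1", 5000, 6000)], layout=layout)
        frags = ev.IntervalSet([ev.GenomicInterval("chr1", 100, 200),   # in TE, no peak
                                ev.GenomicInterval("chr1", 5100, 5200)])  # in peak only
        counts, n_total = ev.reads_per_erv_type(frags, peaks, te)
        assert counts["RLTR10"] == 0 and n_total == 1

    def test_empty_peaks_warn(self, layout):
        te = [ev.TECopy(ev.GenomicInterval("chr1", 0, 1000), "RLTR10", "LTR",
                        "ERVK", 5000)]
        frags = ev.IntervalSet([ev.GenomicInterval("chr1", 100, 200)])
        with pytest.warns(UserWarning, match="empty"):
            counts, n_total = ev.reads_per_erv_type(frags, ev.IntervalSet([]), te)
        assert counts == {"RLTR10": 0} and n_total == 0


class TestSelectAccessibleErvLoci:
    def test_selection_and_monotonicity(self, small_data):
        truth = small_data["truth"]["peaks"]
        table = ev.select_accessible_erv_loci(
            small_data["te"], small_data["peaks"],
            [(t.chrom, t.tss) for t in small_data["assembled"]])
        # every copy of a planted-enriched type is accessible at every stage
        enriched = set(truth["enrichment_folds"])
        for te_type in enriched:
            n_copies = sum(1 for c in small_data["te"] if c.type == te_type)
            for st in small_data["peaks"].stages:
                sub = table[(table.stage == st) & (table.erv_type == te_type)]
                assert len(sub) == n_copies
        assert set(table.proximity) <= {"proximal", "distal"}

    def test_no_peak_overlap_excluded(self, layout):
        te = [ev.TECopy(ev.GenomicInterval("chr1", 0, 500), "MTA_Mm", "LTR",
                        "ERVL-MaLR", 3000)]
        peaks = ev.StagePeakSets(
            stages=["NGO"],
            peaks={"NGO": ev.IntervalSet([ev.GenomicInterval("chr1", 10_000, 11_000)],
                                         layout=layout)})
        assert ev.select_accessible_erv_loci(te, peaks, []).empty


class TestStudies:
    def test_power_study_planted_fold(self):
        out = ev.power_study(p_type=0.01, density_fold=4.0, n_total=10_000,
                             n_replicates=50, seed=2)
        assert out["rate"] >= 0.95

    def test_type_i_rate_near_alpha(self):
        out = ev.type_i_error_study([0.02] * 10, n_total=200_000,
                                    n_replicates=100, seed=3)
        lo, hi = stats.binom.interval(0.99, out["trials"], 0.05)
        assert lo / out["trials"] <= out["rate"] <= hi / out["trials"]


class TestNeighborGeneCompare:
    def make_expr(self, values_a, values_b):
        import pandas as pd
        ids = [f"a{i}" for i in range(len(values_a))] + \
              [f"b{i}" for i in range(len(values_b))]
        df = pd.DataFrame({"GO_rep1": list(values_a) + list(values_b)}, index=ids)
        stages = pd.Series({"GO_rep1": "GO"})
        e = ev.ExpressionMatrix(df, "TPM", stages)
        return e, [f"a{i}" for i in range(len(values_a))], \
            [f"b{i}" for i in range(len(values_b))]

    def test_identical_groups_symmetric(self):
        rng = np.random.default_rng(30)
        vals = rng.normal(10, 2, 100)
        e, ga, gb = self.make_expr(vals, vals)
        r = ev.neighbor_gene_compare(ga, gb, e, "GO")
        assert r["ranksum_p"] > 0.99 and abs(r["median_a"] - r["median_b"]) < 1e-12

    def test_shift_detected(self):
        rng = np.random.default_rng(31)
        base = rng.normal(10, 2, 200)
        e, ga, gb = self.make_expr(base, base + 10)
        r = ev.neighbor_gene_compare(ga, gb, e, "GO")
        assert r["ranksum_p"] < 0.001 and r["welch_t_p"] < 0.001

    def test_label_swap_leaves_two_sided_p_unchanged(self):
        rng = np.random.default_rng(32)
        e, ga, gb = self.make_expr(rng.normal(5, 1, 50), rng.normal(6, 1, 50))
        r1 = ev.neighbor_gene_compare(ga, gb, e, "GO")
        r2 = ev.neighbor_gene_compare(gb, ga, e, "GO")
        assert r1["ranksum_p"] == pytest.approx(r2["ranksum_p"])
        assert r1["welch_t_p"] == pytest.approx(r2["welch_t_p"])

    def test_small_group_rejected(self):
        e, ga, gb = self.make_expr([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="2 genes"):
            ev.neighbor_gene_compare(ga, gb, e, "GO")
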