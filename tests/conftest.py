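import numpy as np
import pytest

import ervatac as ev


@pytest.fixture(scope="session")
def small_data():
    """One generated small scenario shared across the suite (seed fixed)."""
    return ev.generate_scenario(ev.small_scenario(seed=11))


@pytest.fixture()
def layout():
    return ev.GenomeLayout({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture()
def config():
    return ev.AnalysisConfig()


def random_interval_set(rng, layout, n, max_len=500, stranded=False):
    ivs = []
    for _ in range(n):
        chrom = layout.chromosomes[int(rng.integers(len(layout.chromosomes)))]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, layout.length(chrom) - length + 1))
        strand = ["+", "-", "."][int(rng.integers(3))] if stranded else "."
        ivs.append(ev.GenomicInterval(chrom, start, start + length, strand))
    return ev.IntervalSet(ivs, layout=layout)


def brute_force_intersect(a, b, same_strand=False):
    """Quadratic oracle for interval intersection."""
    pairs = []
    for ia in sorted(a.intervals, key=lambda i: (i.chrom, i.start, i.end)):
        for ib in b.intervals:
            if ia.chrom != ib.chrom:
                continue
            ov = min(ia.end, ib.end) - max(ia.start, ib.start)
            if ov < 1:
                continue
            if same_strand and (ia.strand == "." or ib.strand == "." or
                                ia.strand != ib.strand):
                continue
            pairs.append((ia, ib, ov))
    return pairs


def brute_force_covered(query, intervals):
    """Per-base oracle for union coverage of a query interval."""
    mask = np.zeros(query.end - query.start, dtype=bool)
    for iv in intervals:
        if iv.chrom != query.chrom:
            continue
        lo = max(iv.start, query.start) - query.start
        hi = min(iv.end, query.end) - query.start
        if hi > lo:
            mask[lo:hi] = True
    return int(mask.sum())
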