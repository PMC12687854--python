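"""Synthetic-data generator with planted ground truth.

Every pipeline input — genome layout, RepeatMasker-style TE annotation,
reference and "assembled" transcript sets, per-stage peak and fragment sets,
and a negative-binomial count matrix with ERCC-like spike-ins — can be drawn
from a :class:`ScenarioSpec`, together with a truth ledger holding the
planted labels (novelty level, TE-derived TSS, presence pattern, enriched
ERV type, per-stage fold change).  The generator is a pure function of the
spec including its seed: the global seed is split into fixed per-component
child seeds, so changing e.g. the fragment model never perturbs the
transcript draw.

What it emulates / does not: interval geometry, family structure and count
noise of the study's data, at desk scale; it does not simulate sequences,
mappability, TE insertion ages, or peak-caller artifacts.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chromatin import CLASS_OF_PATTERN, StagePeakSets
from .intervals import (GenomeLayout, GenomicInterval, IntervalSet,
                        write_bed, write_repeatmasker_out)
from .te_annotation import TECopy
from .transcripts import TranscriptModel
from .expression import CountMatrix

ATAC_STAGES = ("E18O", "P1O", "NGO")
ALL_STAGES = ("E18O", "P1O", "NGO", "GO")

# family -> (repeat class, type names); ERV families mirror the mouse
# LTR taxonomy highlighted by the analysis (RLTR10* in ERVK, MT*/ORR1 in
# ERVL-MaLR), the rest provide non-ERV background.
DEFAULT_FAMILIES: dict[str, tuple[str, tuple[str, ...]]] = {
    "ERVK": ("LTR", ("RLTR10", "RLTR10A", "RLTR10-int", "RLTR9", "RLTR11",
                     "RLTR12", "RLTR13", "RLTR45", "IAPEz-int", "IAPLTR1_Mm")),
    "ERVL": ("LTR", ("MERVL-int", "MT2_Mm", "ERVL-B4", "ERVL-E")),
    "ERVL-MaLR": ("LTR", ("MTA_Mm", "MTB", "MTC", "MTD", "MTE", "ORR1A0")),
    "L1": ("LINE", ("L1Md_A", "L1Md_T")),
    "B1": ("SINE", ("B1_Mm",)),
    "hAT-Charlie": ("DNA", ("Charlie1",)),
}

PATTERN_OF_CLASS = {v: k for k, v in CLASS_OF_PATTERN.items()}


@dataclass
class TESpec:
    families: dict = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    copies_per_type: int = 30
    length_range: tuple[int, int] = (150, 500)
    sw_range: tuple[int, int] = (1200, 8000)
    low_sw_fraction: float = 0.0   # fraction of copies drawn below the SW filter


@dataclass
class TranscriptSpec:
    n_genes: int = 300
    novel_fraction: float = 0.2            # genes absent from the reference
    novel_isoform_fraction: float = 0.1    # known genes with an extra intron chain
    te_promoter_fraction: float = 0.3      # TSS planted inside a same-strand ERV
    exon_count_range: tuple[int, int] = (1, 3)
    exon_length_range: tuple[int, int] = (150, 300)
    intron_length_range: tuple[int, int] = (100, 400)
    gap_range: tuple[int, int] = (100, 400)


@dataclass
class PeakSpec:
    stages: tuple[str, ...] = ATAC_STAGES
    n_regions: int = 600
    length_range: tuple[int, int] = (200, 400)
    # mixture over the seven presence classes (3-stage patterns)
    class_weights: dict = field(default_factory=lambda: {
        1: 0.10, 2: 0.10, 3: 0.20, 4: 0.20, 5: 0.25, 6: 0.05, 7: 0.10})
    go_primed_fraction: float = 0.6        # NGO regions shared with GO
    n_go_specific: int = 100
    include_te_peaks: bool = True          # enriched-type copies accessible at all stages


@dataclass
class FragmentSpec:
    n_per_stage: int = 20000
    length: int = 100
    enrichment_folds: dict = field(default_factory=lambda: {
        "RLTR10": 4.0, "MTA_Mm": 4.0})


@dataclass
class CountSpec:
    n_genes: int = 2000
    stages: tuple[str, ...] = ALL_STAGES
    replicates: int = 3
    baseline_mean_range: tuple[float, float] = (50.0, 500.0)
    # archetype per-stage fold profiles; genes are split evenly across groups
    group_profiles: tuple = ((5.0, 1.0, 1.0, 1.0), (1.0, 5.0, 1.0, 1.0),
                             (1.0, 1.0, 5.0, 1.0), (1.0, 1.0, 1.0, 5.0))
    dispersion: float = 0.1
    n_spikeins: int = 92  # the ERCC spike-in mix contains 92 species
    spikein_mean_range: tuple[float, float] = (20.0, 2000.0)
    library_scale_sigma: float = 0.3
    gene_length_range: tuple[int, int] = (500, 3000)
    spikein_length_range: tuple[int, int] = (300, 2000)


@dataclass
class ScenarioSpec:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    te: TESpec = field(default_factory=TESpec)
    transcripts: TranscriptSpec = field(default_factory=TranscriptSpec)
    peaks: PeakSpec = field(default_factory=PeakSpec)
    fragments: FragmentSpec = field(default_factory=FragmentSpec)
    counts: CountSpec = field(default_factory=CountSpec)


def small_scenario(seed: int = 0) -> ScenarioSpec:
    """The default desk-scale scenario: 2 x 1 Mb chromosomes, 24 TE types
    (20 of them ERV), 300 gene models, 3 ATAC stages + GO, 4 x 3 count
    samples.  Runs end to end in seconds."""
    return ScenarioSpec(seed=seed)


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("genome", "te", "transcripts", "peaks", "fragments", "counts")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


class _Occupancy:
    """Sorted non-overlapping occupied intervals per chromosome."""

    def __init__(self):
        self._by: dict[str, list[tuple[int, int]]] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        rows = self._by.get(chrom, [])
        i = bisect.bisect_left(rows, (start, start))
        if i < len(rows) and rows[i][0] < end:
            return False
        if i > 0 and rows[i - 1][1] > start:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        rows = self._by.setdefault(chrom, [])
        bisect.insort(rows, (start, end))

    def free_segments(self, layout: GenomeLayout) -> list[tuple[str, int, int]]:
        out = []
        for chrom in layout.chromosomes:
            pos = 0
            for s, e in self._by.get(chrom, []):
                if s > pos:
                    out.append((chrom, pos, s))
                pos = max(pos, e)
            if pos < layout.length(chrom):
                out.append((chrom, pos, layout.length(chrom)))
        return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_genome(spec: ScenarioSpec) -> GenomeLayout:
    if spec.n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    return GenomeLayout([(f"chr{i + 1}", spec.chromosome_length)
                         for i in range(spec.n_chromosomes)])


def plant_te_annotation(spec: ScenarioSpec, layout: GenomeLayout):
    """Place non-overlapping TE copies uniformly; returns (copies, truth).

    Truth records per-type genomic bp and fraction (the p_type ground truth
    for the enrichment null) plus the low-SW planting, all recomputable from
    the output.
    """
    rng = _child_rngs(spec.seed)["te"]
    ts = spec.te
    total_bp_request = sum(len(types) for _, types in ts.families.values()) \
        * ts.copies_per_type * (ts.length_range[0] + ts.length_range[1]) / 2
    if total_bp_request > 0.8 * layout.total_bp:
        raise ValueError("requested TE bp exceeds 80% of the genome; lower the density")
    chroms = layout.chromosomes
    chrom_len = np.array([layout.length(c) for c in chroms], dtype=float)
    p_chrom = chrom_len / chrom_len.sum()
    occ = _Occupancy()
    copies: list[TECopy] = []
    for family in ts.families:
        te_class, types = ts.families[family]
        for te_type in types:
            for _ in range(ts.copies_per_type):
                length = int(rng.integers(ts.length_range[0], ts.length_range[1] + 1))
                low = rng.random() < ts.low_sw_fraction
                if low:
                    bound = 500 if te_class in ("SINE", "DNA") else 1000
                    sw = int(rng.integers(50, bound + 1))
                else:
                    sw = int(rng.integers(ts.sw_range[0], ts.sw_range[1] + 1))
                placed = False
                for _attempt in range(200):
                    chrom = chroms[int(rng.choice(len(chroms), p=p_chrom))]
                    start = int(rng.integers(0, layout.length(chrom) - length + 1))
                    if occ.is_free(chrom, start, start + length):
                        occ.add(chrom, start, start + length)
                        strand = "+" if rng.random() < 0.5 else "-"
                        copies.append(TECopy(
                            GenomicInterval(chrom, start, start + length, strand),
                            type=te_type, te_class=te_class, family=family,
                            sw_score=sw))
                        placed = True
                        break
                if not placed:
                    raise RuntimeError(
                        f"could not place a copy of {te_type} after 200 tries; "
                        "lower copies_per_type or lengths")
    bp_per_type: dict[str, int] = {}
    for c in copies:
        bp_per_type[c.type] = bp_per_type.get(c.type, 0) + c.interval.length
    truth = {
        "type_bp": bp_per_type,
        "type_fraction": {t: bp / layout.total_bp for t, bp in bp_per_type.items()},
        "family_of_type": {c.type: c.family for c in copies},
        "class_of_type": {c.type: c.te_class for c in copies},
    }
    return copies, truth


def _gene_body(rng, tspec: TranscriptSpec, n_exons: int):
    exon_lens = [int(rng.integers(*tspec.exon_length_range)) for _ in range(n_exons)]
    intron_lens = [int(rng.integers(*tspec.intron_length_range))
                   for _ in range(n_exons - 1)]
    return exon_lens, intron_lens


def _exons_from_tss(tss: int, strand: str, exon_lens, intron_lens):
    """Exon tuples laid out in transcription direction starting at the TSS."""
    if strand == "+":
        exons, pos = [], tss
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el + (intron_lens[i] if i < len(intron_lens) else 0)
        return tuple(exons)
    exons, pos = [], tss + 1
    for i, el in enumerate(exon_lens):
        exons.append((pos - el, pos))
        pos -= el + (intron_lens[i] if i < len(intron_lens) else 0)
    return tuple(sorted(exons))


def plant_transcripts(spec: ScenarioSpec, layout: GenomeLayout, te):
    """Reference + assembled transcript sets with planted novelty and TE-TSS.

    Exact planting: ``round(fraction * n_genes)`` genes of each kind.
    TE-promoter genes take their TSS inside an existing same-strand ERV copy
    so that the copy covers the full 100 bp TSS window (verified at
    generation time via ``te_at_tss``); all other gene bodies live in
    TE-free space, so their TSS windows are TE-free.

    Returns (reference, assembled, truth) where truth maps gene ids to
    novelty level and TE-promoter type.
    """
    from .te_annotation import AnalysisConfig, te_at_tss

    rng = _child_rngs(spec.seed)["transcripts"]
    tspec = spec.transcripts
    n = tspec.n_genes
    n_novel = round(tspec.novel_fraction * n)
    n_iso = round(tspec.novel_isoform_fraction * n)
    n_tep = round(tspec.te_promoter_fraction * n)

    perm = rng.permutation(n)
    novelty = np.array(["known"] * n, dtype=object)
    novelty[perm[:n_novel]] = "novel_gene"
    novelty[perm[n_novel:n_novel + n_iso]] = "novel_isoform"
    tep = np.zeros(n, dtype=bool)
    tep[rng.permutation(n)[:n_tep]] = True

    erv_copies = [c for c in te if c.family.startswith("ERV") and c.interval.length >= 120]
    rng.shuffle(erv_copies)
    gene_occ = _Occupancy()   # reserved gene spans (TSS margin included)
    combined = _Occupancy()   # TE copies + gene spans, for TE-free placement
    for c in te:
        combined.add(c.interval.chrom, c.interval.start, c.interval.end)

    genes = []  # (gene index, chrom, strand, exons, te_type or None)
    copy_cursor = 0
    margin = 60  # keeps foreign TSS windows clear of TE edges
    for gi in np.flatnonzero(tep):
        n_exons = int(rng.integers(tspec.exon_count_range[0],
                                   tspec.exon_count_range[1] + 1))
        exon_lens, intron_lens = _gene_body(rng, tspec, n_exons)
        span = sum(exon_lens) + sum(intron_lens)
        placed = False
        while copy_cursor < len(erv_copies):
            c = erv_copies[copy_cursor]
            copy_cursor += 1
            chrom, strand = c.interval.chrom, c.interval.strand
            if strand == "+":
                tss = c.interval.start + 60
                lo, hi = tss, tss + span
            else:
                tss = c.interval.end - 61
                lo, hi = tss + 1 - span, tss + 1
            if lo - margin < 0 or hi + margin > layout.length(chrom):
                continue
            # the gene body may run through TE copies but not through
            # previously reserved gene spans
            if not gene_occ.is_free(chrom, lo - margin, hi + margin):
                continue
            exons = _exons_from_tss(tss, strand, exon_lens, intron_lens)
            gene_occ.add(chrom, lo - margin, hi + margin)
            combined.add(chrom, lo - margin, hi + margin)
            genes.append((gi, chrom, strand, exons, c.type))
            placed = True
            break
        if not placed:
            raise RuntimeError("not enough ERV copies to host planted TE promoters")

    # non-TE genes go into TE-free segments, sequentially with random gaps
    free = combined.free_segments(layout)
    rng.shuffle(free)
    remaining = [gi for gi in range(n) if not tep[gi]]
    ri = 0
    for chrom, seg_lo, seg_hi in free:
        pos = seg_lo + margin
        while ri < len(remaining) and pos < seg_hi - margin:
            gi = remaining[ri]
            n_exons = int(rng.integers(tspec.exon_count_range[0],
                                       tspec.exon_count_range[1] + 1))
            exon_lens, intron_lens = _gene_body(rng, tspec, n_exons)
            span = sum(exon_lens) + sum(intron_lens)
            gap = int(rng.integers(*tspec.gap_range))
            if pos + gap + span > seg_hi - margin:
                break
            start = pos + gap
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else start + span - 1
            exons = _exons_from_tss(tss, strand, exon_lens, intron_lens)
            genes.append((gi, chrom, strand, exons, None))
            pos = start + span
            ri += 1
        if ri >= len(remaining):
            break
    if ri < len(remaining):
        raise RuntimeError(
            f"insufficient TE-free space: placed {ri} of {len(remaining)} "
            "non-TE genes; enlarge the genome or reduce n_genes")

    reference, assembled, truth = [], [], {}
    for gi, chrom, strand, exons, te_type in sorted(genes):
        gid = f"g{gi:05d}"
        level = novelty[gi]
        if level in ("known", "novel_isoform"):
            reference.append(TranscriptModel(f"{gid}.ref", gid, chrom, strand,
                                             exons, source="reference"))
        if level == "known":
            assembled.append(TranscriptModel(f"{gid}.asm", gid, chrom, strand,
                                             exons, source="assembled"))
        elif level == "novel_isoform":
            assembled.append(TranscriptModel(f"{gid}.asm", gid, chrom, strand,
                                             _split_last_exon(exons, strand),
                                             source="assembled"))
        else:
            assembled.append(TranscriptModel(f"{gid}.asm", gid, chrom, strand,
                                             exons, source="assembled"))
        truth[gid] = {"novelty": str(level), "te_promoter": te_type is not None,
                      "te_type": te_type, "strand": strand, "chrom": chrom}

    # generation-time verification of every planted TE-derived TSS
    cfg = AnalysisConfig()
    for t in assembled:
        if truth[t.gene_id]["te_promoter"]:
            hit = te_at_tss(t, te, cfg, layout=layout)
            if hit is None or hit[0].type != truth[t.gene_id]["te_type"]:
                raise AssertionError(
                    f"planted TE promoter for {t.gene_id} failed verification")
    return reference, assembled, truth


def _split_last_exon(exons, strand):
    """Insert one extra intron into the terminal exon -> different chain."""
    exons = list(exons)
    idx = len(exons) - 1 if strand == "+" else 0
    s, e = exons[idx]
    if e - s < 90:
        raise ValueError("exon too short to split")
    third = (e - s) // 3
    exons[idx:idx + 1] = [(s, s + third), (s + third + 30, e)]
    return tuple(sorted(exons))


def plant_peaks_and_fragments(spec: ScenarioSpec, layout: GenomeLayout, te,
                              transcripts=None):
    """Per-stage peak sets realizing a planted presence-pattern mixture, a GO
    peak set with a planted primed fraction, and per-stage fragment sets with
    planted per-ERV-type read enrichment.

    Universe regions are placed non-overlapping with >= 2 bp separation so the
    merged universe reproduces them exactly.  Each region draws a presence
    class from ``class_weights`` (exact planting by largest-remainder
    rounding); a stage's peak set contains the region verbatim where the
    pattern is '+'.  With ``include_te_peaks`` every copy of each
    planted-enriched type is additionally accessible at all stages (these
    peaks are recorded separately in the truth and carry the all-present
    pattern).

    Fragments are drawn per stage from a two-component model: uniform
    background over the genome, plus, inside the copies of each enriched
    type, extra density so the type's total density is ``fold`` times
    background.

    Returns (StagePeakSets, go_peaks: IntervalSet,
    fragments: dict stage -> IntervalSet, truth).
    """
    rng = _child_rngs(spec.seed)["peaks"]
    frng = _child_rngs(spec.seed)["fragments"]
    ps, fs = spec.peaks, spec.fragments
    if len(ps.stages) != 3:
        raise ValueError("the presence-class mixture is defined over 3 stages")

    occ = _Occupancy()
    # mixture regions stay clear of every TE copy so that TE-accessibility
    # peaks never merge with them and the planted patterns survive merging
    for c in te:
        occ.add(c.interval.chrom, c.interval.start - 2, c.interval.end + 2)
    chroms = layout.chromosomes
    chrom_len = np.array([layout.length(c) for c in chroms], dtype=float)
    p_chrom = chrom_len / chrom_len.sum()
    regions = []
    for _ in range(ps.n_regions):
        length = int(rng.integers(ps.length_range[0], ps.length_range[1] + 1))
        for _attempt in range(200):
            chrom = chroms[int(rng.choice(len(chroms), p=p_chrom))]
            start = int(rng.integers(0, layout.length(chrom) - length + 1))
            if occ.is_free(chrom, start - 2, start + length + 2):
                occ.add(chrom, start - 2, start + length + 2)
                regions.append(GenomicInterval(chrom, start, start + length))
                break
        else:
            raise RuntimeError("could not place peak universe region; lower n_regions")

    # exact class counts by largest remainder, then a seeded shuffle
    classes = sorted(ps.class_weights)
    raw = np.array([ps.class_weights[c] for c in classes], dtype=float)
    raw = raw / raw.sum() * ps.n_regions
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: ps.n_regions - counts.sum()]:
        counts[i] += 1
    assigned = np.repeat(classes, counts)
    rng.shuffle(assigned)

    stage_peaks: dict[str, list[GenomicInterval]] = {st: [] for st in ps.stages}
    region_truth = []
    for iv, cls in zip(regions, assigned):
        pattern = PATTERN_OF_CLASS[int(cls)]
        for st, present in zip(ps.stages, pattern):
            if present:
                stage_peaks[st].append(iv)
        region_truth.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                             "class": int(cls),
                             "pattern": "".join("+" if p else "-" for p in pattern)})

    te_peak_truth = []
    if ps.include_te_peaks and fs.enrichment_folds:
        enriched = set(fs.enrichment_folds)
        for c in te:
            if c.type in enriched:
                for st in ps.stages:
                    stage_peaks[st].append(c.interval)
                te_peak_truth.append({"chrom": c.interval.chrom,
                                      "start": c.interval.start,
                                      "end": c.interval.end, "type": c.type})

    peak_sets = StagePeakSets(
        stages=list(ps.stages),
        peaks={st: IntervalSet(ivs, layout=layout) for st, ivs in stage_peaks.items()})

    # GO peaks: a planted fraction of the NGO regions (identical coordinates,
    # i.e. primed accessible chromatin) plus GO-specific regions
    ngo = stage_peaks[ps.stages[-1]]
    n_primed = round(ps.go_primed_fraction * len(ngo))
    order = rng.permutation(len(ngo))
    go_ivs = [ngo[i] for i in sorted(order[:n_primed])]
    primed_truth = [{"chrom": iv.chrom, "start": iv.start, "end": iv.end}
                    for iv in go_ivs]
    for _ in range(ps.n_go_specific):
        length = int(rng.integers(ps.length_range[0], ps.length_range[1] + 1))
        for _attempt in range(200):
            chrom = chroms[int(rng.choice(len(chroms), p=p_chrom))]
            start = int(rng.integers(0, layout.length(chrom) - length + 1))
            if occ.is_free(chrom, start - 2, start + length + 2):
                occ.add(chrom, start - 2, start + length + 2)
                go_ivs.append(GenomicInterval(chrom, start, start + length))
                break
        else:
            raise RuntimeError("could not place GO-specific peak")
    go_peaks = IntervalSet(go_ivs, layout=layout)

    fragments = {st: sample_fragments(layout, te, fs.enrichment_folds,
                                      fs.n_per_stage, fs.length, frng)
                 for st in ps.stages}

    truth = {"regions": region_truth, "te_peaks": te_peak_truth,
             "primed": primed_truth,
             "enrichment_folds": dict(fs.enrichment_folds)}
    return peak_sets, go_peaks, fragments, truth


def sample_fragments(layout: GenomeLayout, te, enrichment_folds: dict,
                     n_fragments: int, length: int, rng) -> IntervalSet:
    """Two-component fragment sampler: uniform background plus planted
    per-type enrichment (fold x background density inside the type's copies)."""
    chroms = layout.chromosomes
    chrom_len = np.array([layout.length(c) for c in chroms], dtype=np.int64)
    g = float(chrom_len.sum())
    comp_types = [t for t, f in sorted(enrichment_folds.items()) if f > 1.0]
    copies_of = {t: [c.interval for c in te if c.type == t] for t in comp_types}
    weights = [g] + [(enrichment_folds[t] - 1.0) *
                     sum(iv.length for iv in copies_of[t]) for t in comp_types]
    w = np.asarray(weights, dtype=float)
    comp = rng.choice(len(w), size=n_fragments, p=w / w.sum())
    out = []
    cum = np.cumsum(chrom_len)
    for k in comp:
        if k == 0:
            gpos = int(rng.integers(0, int(g)))
            ci = int(np.searchsorted(cum, gpos, side="right"))
            chrom = chroms[ci]
            center = gpos - (int(cum[ci - 1]) if ci else 0)
        else:
            ivs = copies_of[comp_types[k - 1]]
            lens = np.array([iv.length for iv in ivs], dtype=float)
            iv = ivs[int(rng.choice(len(ivs), p=lens / lens.sum()))]
            center = int(rng.integers(iv.start, iv.end))
            chrom = iv.chrom
        lo = max(0, center - length // 2)
        hi = min(layout.length(chrom), lo + length)
        lo = max(0, hi - length)
        out.append(GenomicInterval(chrom, lo, hi))
    return IntervalSet(out, layout=layout)


def plant_counts_with_ercc(spec: ScenarioSpec, gene_ids=None):
    """Negative-binomial count matrix with ERCC-like spike-ins.

    Gene counts ~ NB(mean = baseline x stage fold x library scale,
    dispersion); spike-in counts ~ NB(mean = fixed per-cell abundance x
    library scale, dispersion) — the spike-in expectation is invariant
    across stages by construction, which is what makes per-cell
    normalization identifiable.  Library scales are log-normal per sample.

    Returns (CountMatrix, truth) with planted group labels, per-stage fold
    profiles, and library scales.
    """
    rng = _child_rngs(spec.seed)["counts"]
    cs = spec.counts
    if cs.dispersion <= 0:
        raise ValueError("NB dispersion must be positive")
    n_stages = len(cs.stages)
    profiles = np.asarray(cs.group_profiles, dtype=float)
    if profiles.shape[1] != n_stages:
        raise ValueError("group profile length must match the stage count")
    n_groups = len(profiles)
    groups = np.repeat(np.arange(n_groups), -(-cs.n_genes // n_groups))[: cs.n_genes]
    rng.shuffle(groups)
    baseline = np.exp(rng.uniform(np.log(cs.baseline_mean_range[0]),
                                  np.log(cs.baseline_mean_range[1]), cs.n_genes))
    spike_mean = np.exp(rng.uniform(np.log(cs.spikein_mean_range[0]),
                                    np.log(cs.spikein_mean_range[1]), cs.n_spikeins))
    samples, stages_col, scales = [], [], []
    for st in cs.stages:
        for r in range(1, cs.replicates + 1):
            samples.append(f"{st}_rep{r}")
            stages_col.append(st)
            scales.append(float(np.exp(rng.normal(0.0, cs.library_scale_sigma))))
    inv_disp = 1.0 / cs.dispersion

    def nb_draw(mean: np.ndarray) -> np.ndarray:
        p = inv_disp / (inv_disp + mean)
        return rng.negative_binomial(inv_disp, p)

    data = np.zeros((cs.n_genes + cs.n_spikeins, len(samples)), dtype=np.int64)
    for j, (st, scale) in enumerate(zip(stages_col, scales)):
        si = cs.stages.index(st)
        gene_mean = baseline * profiles[groups, si] * scale
        data[: cs.n_genes, j] = nb_draw(gene_mean)
        data[cs.n_genes:, j] = nb_draw(spike_mean * scale)

    if gene_ids is None:
        gene_ids = [f"gene{i:05d}" for i in range(cs.n_genes)]
    else:
        gene_ids = list(gene_ids)[: cs.n_genes]
        gene_ids += [f"gene{i:05d}" for i in range(len(gene_ids), cs.n_genes)]
    spike_ids = [f"ERCC-{i:05d}" for i in range(cs.n_spikeins)]
    index = pd.Index(gene_ids + spike_ids, name="feature_id")
    counts = pd.DataFrame(data, index=index, columns=samples)
    lengths = pd.Series(
        np.concatenate([
            rng.integers(*cs.gene_length_range, cs.n_genes),
            rng.integers(*cs.spikein_length_range, cs.n_spikeins)]),
        index=index)
    is_spike = pd.Series([False] * cs.n_genes + [True] * cs.n_spikeins, index=index)
    stages = pd.Series(stages_col, index=samples)
    m = CountMatrix(counts, lengths, is_spike, stages)
    truth = {
        "group": dict(zip(gene_ids, (int(v) + 1 for v in groups))),
        "group_profiles": profiles.tolist(),
        "stages": list(cs.stages),
        "library_scale": dict(zip(samples, scales)),
        "spikein_mean": dict(zip(spike_ids, spike_mean.tolist())),
    }
    return m, truth


def plant_expression_archetypes(n_per_group: int = 100, noise_sd: float = 0.1,
                                seed: int = 0, stages=ALL_STAGES):
    """Stage-mean expression archetypes for clustering tests: one archetype
    peaking at each stage, Gaussian noise on the z-scale.

    Returns (ExpressionMatrix with one sample per stage, truth labels)."""
    from .expression import ExpressionMatrix

    rng = np.random.default_rng(seed)
    k = len(stages)
    base = np.full((k, k), 1.0)
    np.fill_diagonal(base, 6.0)
    rows, labels, ids = [], [], []
    for g in range(k):
        for i in range(n_per_group):
            rows.append(base[g] + rng.normal(0.0, noise_sd, k))
            labels.append(g + 1)
            ids.append(f"gene{g}_{i:04d}")
    values = pd.DataFrame(np.maximum(np.asarray(rows), 0.0), index=ids,
                          columns=list(stages))
    stages_s = pd.Series(list(stages), index=list(stages))
    e = ExpressionMatrix(values=values, unit="TPM", stages=stages_s)
    return e, pd.Series(labels, index=ids, name="group")


# ---------------------------------------------------------------------------
# scenario orchestration and file export
# ---------------------------------------------------------------------------


def generate_scenario(spec: ScenarioSpec) -> dict:
    """Run every generator for one spec; returns a dict of all artifacts."""
    layout = make_genome(spec)
    te, te_truth = plant_te_annotation(spec, layout)
    reference, assembled, tx_truth = plant_transcripts(spec, layout, te)
    peak_sets, go_peaks, fragments, peak_truth = plant_peaks_and_fragments(
        spec, layout, te, assembled)
    count_matrix, count_truth = plant_counts_with_ercc(
        spec, gene_ids=sorted({t.gene_id for t in assembled}))
    return {
        "layout": layout, "te": te, "reference": reference,
        "assembled": assembled, "peaks": peak_sets, "go_peaks": go_peaks,
        "fragments": fragments, "counts": count_matrix,
        "truth": {"te": te_truth, "transcripts": tx_truth,
                  "peaks": peak_truth, "counts": count_truth,
                  "seed": spec.seed},
    }


def write_scenario(data: dict, outdir) -> None:
    """Write a generated scenario in the standard formats the pipeline reads."""
    from .transcripts import write_gtf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data["layout"].write(outdir / "genome.chrom.sizes")
    write_repeatmasker_out(data["te"], outdir / "te_annotation.out")
    write_gtf(data["reference"], outdir / "reference.gtf")
    write_gtf(data["assembled"], outdir / "assembled.gtf")
    for st in data["peaks"].stages:
        write_bed(data["peaks"].peaks[st], outdir / f"peaks_{st}.bed")
    write_bed(data["go_peaks"], outdir / "peaks_GO.bed")
    for st, frags in data["fragments"].items():
        write_bed(frags, outdir / f"fragments_{st}.bed")
    data["counts"].write_tsv(outdir / "counts.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(data["truth"], fh, indent=1)

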