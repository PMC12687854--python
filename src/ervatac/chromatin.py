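"""Stage-wise chromatin-accessibility dynamics.

Covers genomic-feature annotation of peaks (promoter/TTS/exon/intron/
intergenic by peak center, promoter = -1 kb..+100 bp of the TSS, TTS =
-100 bp..+1 kb of the termination site, strand-aware), the proximal/distal
split at +-1 kb from TSSs, presence/absence classes of merged peak regions
across three stages, primed accessible chromatin (NGO peaks shared with GO),
nearest-distal-peak distances, observed-vs-expected TE overlap of peaks, and
a minimal signal-over-regions matrix for heatmap-style summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomeLayout, GenomicInterval, IntervalSet, shuffle_intervals
from .te_annotation import AnalysisConfig

# Three-stage presence patterns -> class numbers.  Classes 3 (P1O/NGO
# specific), 4 (NGO specific) and 5 (constitutive) are anchored; the four
# remaining patterns take Classes 1, 2, 6, 7 in a fixed documented order.
CLASS_OF_PATTERN = {
    (True, False, False): 1,
    (True, True, False): 2,
    (False, True, True): 3,
    (False, False, True): 4,
    (True, True, True): 5,
    (True, False, True): 6,
    (False, True, False): 7,
}


@dataclass
class StagePeakSets:
    """Ordered per-stage peak interval sets sharing one genome layout."""

    stages: list[str]
    peaks: dict[str, IntervalSet]

    def __post_init__(self):
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage labels must be unique")
        missing = [s for s in self.stages if s not in self.peaks]
        if missing:
            raise ValueError(f"no peak set for stage(s) {missing}")


@dataclass
class PresenceMatrix:
    """Merged peak universe with per-stage boolean presence and class labels."""

    universe: IntervalSet
    stages: list[str]
    presence: np.ndarray          # (n_regions, n_stages) bool
    classes: list                 # int class number (3 stages) or bit-string

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iv, pres, cls in zip(self.universe.sorted_intervals(),
                                 self.presence, self.classes):
            rows.append({"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                         "pattern": "".join("+" if p else "-" for p in pres),
                         "class": cls})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FeatureAnnotation:
    region_id: str
    category: str                 # promoter | TTS | exon | intron | intergenic
    nearest_gene: str | None
    distance_to_tss: int | None   # signed, strand-aware (positive = downstream)


class GeneIndex:
    """Per-chromosome arrays over transcripts for fast center queries."""

    def __init__(self, transcripts):
        self.transcripts = list(transcripts)
        by: dict[str, list[int]] = {}
        for i, t in enumerate(self.transcripts):
            by.setdefault(t.chrom, []).append(i)
        self.by_chrom = {}
        for chrom, idxs in by.items():
            tss = np.array([self.transcripts[i].tss for i in idxs], dtype=np.int64)
            order = np.argsort(tss, kind="stable")
            self.by_chrom[chrom] = {
                "idx": np.array(idxs)[order],
                "tss": tss[order],
            }

    def nearest_tss(self, chrom: str, pos: int):
        """(transcript, |pos - TSS|) minimizing distance; ties -> smaller gene id."""
        if chrom not in self.by_chrom:
            return None, None
        rec = self.by_chrom[chrom]
        tss = rec["tss"]
        j = int(np.searchsorted(tss, pos))
        cands = [c for c in (j - 1, j) if 0 <= c < len(tss)]
        best = None
        for c in cands:
            d = abs(pos - int(tss[c]))
            # widen to all ties at the same distance
            lo = c
            while lo - 1 >= 0 and abs(pos - int(tss[lo - 1])) == d:
                lo -= 1
            hi = c
            while hi + 1 < len(tss) and abs(pos - int(tss[hi + 1])) == d:
                hi += 1
            for k in range(lo, hi + 1):
                t = self.transcripts[int(rec["idx"][k])]
                dk = abs(pos - int(tss[k]))
                key = (dk, t.gene_id)
                if best is None or key < best[0]:
                    best = (key, t)
        if best is None:
            return None, None
        return best[1], best[0][0]


def _in_window(rel: int, upstream: int, downstream: int) -> bool:
    # relative coordinate in transcription direction; window [-up, +down)
    return -upstream <= rel < downstream


def annotate_peak_feature(peak: GenomicInterval, genes, config: AnalysisConfig | None = None,
                          index: GeneIndex | None = None) -> FeatureAnnotation:
    """Categorize a peak by its center with priority promoter > TTS > exon > intron.

    Promoter window is [TSS-1000, TSS+100) in transcription direction
    (mirrored on -); TTS window is [TES-100, TES+1000).  Nearest gene
    minimizes |center - TSS| over all transcripts, ties to the smaller gene
    id; the reported distance is signed in the gene's transcription
    direction.
    """
    config = config or AnalysisConfig()
    index = index or GeneIndex(genes)
    center = peak.center
    region_id = peak.name or f"{peak.chrom}:{peak.start}-{peak.end}"
    nearest, _ = index.nearest_tss(peak.chrom, center)
    if nearest is None:
        return FeatureAnnotation(region_id, "intergenic", None, None)
    signed = (center - nearest.tss) if nearest.strand == "+" else (nearest.tss - center)

    is_promoter = is_tts = is_exon = is_intron = False
    rec = index.by_chrom.get(peak.chrom)
    if rec is not None:
        for i in rec["idx"]:
            t = index.transcripts[int(i)]
            rel_tss = (center - t.tss) if t.strand == "+" else (t.tss - center)
            if _in_window(rel_tss, config.promoter_upstream_bp, config.promoter_downstream_bp):
                is_promoter = True
                break
            rel_tes = (center - t.tes) if t.strand == "+" else (t.tes - center)
            if _in_window(rel_tes, config.tts_upstream_bp, config.tts_downstream_bp):
                is_tts = True
            if t.start <= center < t.end:
                if any(s <= center < e for s, e in t.exons):
                    is_exon = True
                else:
                    is_intron = True
    if is_promoter:
        category = "promoter"
    elif is_tts:
        category = "TTS"
    elif is_exon:
        category = "exon"
    elif is_intron:
        category = "intron"
    else:
        category = "intergenic"
    return FeatureAnnotation(region_id, category, nearest.gene_id, signed)


def annotate_peaks(peaks: IntervalSet, genes, config: AnalysisConfig | None = None):
    index = GeneIndex(genes)
    return [annotate_peak_feature(p, genes, config, index=index)
            for p in peaks.sorted_intervals()]


def split_proximal_distal(peaks: IntervalSet, tss_list, radius: int = 1000):
    """Partition peaks into proximal (center within +-radius of any TSS,
    inclusive) and distal.  ``tss_list`` is an iterable of (chrom, pos)."""
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in tss_list:
        by_chrom.setdefault(chrom, []).append(pos)
    sorted_tss = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}
    proximal, distal = [], []
    for p in peaks.sorted_intervals():
        tss = sorted_tss.get(p.chrom)
        if tss is None or len(tss) == 0:
            distal.append(p)
            continue
        c = p.center
        j = int(np.searchsorted(tss, c))
        d = min(abs(c - int(tss[k])) for k in (j - 1, j) if 0 <= k < len(tss))
        (proximal if d <= radius else distal).append(p)
    return (IntervalSet(proximal, layout=peaks.layout),
            IntervalSet(distal, layout=peaks.layout))


def presence_classes(s: StagePeakSets) -> PresenceMatrix:
    """Merged-universe presence/absence profile across stages.

    A universe region is "present" in a stage iff it overlaps (>= 1 bp) a
    peak of that stage.  With exactly three stages the seven possible
    patterns get the canonical class numbers; otherwise the pattern
    bit-string is used as the label.
    """
    all_ivs = [iv for st in s.stages for iv in s.peaks[st]]
    layout = next((s.peaks[st].layout for st in s.stages
                   if s.peaks[st].layout is not None), None)
    universe = IntervalSet(all_ivs, layout=layout).merge()
    merged_by_stage = {st: s.peaks[st].merge() for st in s.stages}
    presence = np.zeros((len(universe), len(s.stages)), dtype=bool)
    regions = universe.sorted_intervals()
    for j, st in enumerate(merged_by_stage):
        mset = merged_by_stage[st]
        for i, iv in enumerate(regions):
            presence[i, j] = mset.covered_bp(iv) >= 1
    classes = []
    for row in presence:
        if not row.any():
            raise AssertionError("universe region absent from every stage")
        if len(s.stages) == 3:
            classes.append(CLASS_OF_PATTERN[tuple(bool(v) for v in row)])
        else:
            classes.append("".join("+" if v else "-" for v in row))
    return PresenceMatrix(universe=universe, stages=list(s.stages),
                          presence=presence, classes=classes)


def primed_peaks(ngo: IntervalSet, go: IntervalSet) -> IntervalSet:
    """NGO peaks sharing >= 1 bp with any GO peak (primed accessible chromatin).

    Output keeps the NGO coordinates."""
    go_merged = go.merge()
    out = [p for p in ngo.sorted_intervals() if go_merged.covered_bp(p) >= 1]
    return IntervalSet(out, layout=ngo.layout)


def nearest_distal_distance(tss: tuple[str, int], distal_peaks: IntervalSet):
    """min |TSS - peak center| over distal peaks on the TSS chromosome; None
    when no distal peak exists there."""
    chrom, pos = tss
    centers = [p.center for p in distal_peaks if p.chrom == chrom]
    if not centers:
        return None
    return min(abs(pos - c) for c in centers)


def nearest_distal_distances(tss_list, distal_peaks: IntervalSet) -> list:
    by_chrom: dict[str, np.ndarray] = {}
    for p in distal_peaks:
        by_chrom.setdefault(p.chrom, []).append(p.center)
    by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}
    out = []
    for chrom, pos in tss_list:
        centers = by_chrom.get(chrom)
        if centers is None or len(centers) == 0:
            out.append(None)
            continue
        j = int(np.searchsorted(centers, pos))
        out.append(min(abs(pos - int(centers[k]))
                       for k in (j - 1, j) if 0 <= k < len(centers)))
    return out


def expected_te_overlap(peaks: IntervalSet, te_coverage: IntervalSet,
                        layout: GenomeLayout, mode: str = "analytic",
                        n_shuffles: int = 100, seed: int = 0) -> dict:
    """Observed vs expected fraction of peaks whose center lies in TE coverage.

    Analytic expectation = TE-covered bp / genome bp (peak centers uniform
    under the null).  Shuffle expectation re-places the peaks with
    :func:`shuffle_intervals` across chromosomes (probability proportional
    to length, matching the genome-uniform null) and reports the mean
    observed fraction with its Monte-Carlo standard error.
    """
    te_coverage = te_coverage if te_coverage.merged else te_coverage.merge()

    def observed_fraction(pset: IntervalSet) -> float:
        n = len(pset)
        if n == 0:
            return float("nan")
        hits = sum(te_coverage.contains_point(p.chrom, p.center) for p in pset)
        return hits / n

    result = {
        "observed": observed_fraction(peaks),
        "expected_analytic": te_coverage.covered_bp_total() / layout.total_bp,
        "n_peaks": len(peaks),
    }
    if mode == "shuffle":
        if n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1 in shuffle mode")
        child = np.random.SeedSequence(seed).generate_state(n_shuffles, dtype=np.uint32)
        fracs = np.array([
            observed_fraction(shuffle_intervals(peaks, layout, int(child[i]),
                                                same_chromosome=False))
            for i in range(n_shuffles)])
        result["expected_shuffle"] = float(fracs.mean())
        result["shuffle_se"] = float(fracs.std(ddof=1) / np.sqrt(n_shuffles)) \
            if n_shuffles > 1 else float("nan")
    return result


def signal_over_regions(fragments: IntervalSet, regions: IntervalSet,
                        flank_bp: int = 0, n_bins: int = 1,
                        scale: float = 1.0) -> np.ndarray:
    """Region-by-bin matrix of scaled fragment-overlap counts.

    Each region is expanded by ``flank_bp`` on both sides and divided into
    ``n_bins`` equal bins; a fragment contributes 1 to every bin it overlaps
    by >= 1 bp.  Values are multiplied by ``scale`` (e.g. a spike-in scale
    factor).  Minus-strand regions are reversed so bin 0 is always 5'.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    frag_idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by: dict[str, list[tuple[int, int]]] = {}
    for f in fragments:
        by.setdefault(f.chrom, []).append((f.start, f.end))
    for chrom, rows in by.items():
        rows.sort()
        arr = np.asarray(rows, dtype=np.int64)
        frag_idx[chrom] = (arr[:, 0], np.sort(arr[:, 1]))
    mat = np.zeros((len(regions), n_bins), dtype=float)
    for i, r in enumerate(regions.sorted_intervals()):
        lo = r.start - flank_bp
        hi = r.end + flank_bp
        edges = lo + (hi - lo) * np.arange(n_bins + 1) / n_bins
        if r.chrom not in frag_idx:
            continue
        starts_sorted, ends_sorted = frag_idx[r.chrom]
        for b in range(n_bins):
            b_lo, b_hi = edges[b], edges[b + 1]
            # fragments with start < bin end and end > bin start
            n_start_before = int(np.searchsorted(starts_sorted, b_hi, side="left"))
            n_end_before = int(np.searchsorted(ends_sorted, b_lo, side="right"))
            mat[i, b] = max(0, n_start_before - n_end_before)
        if r.strand == "-":
            mat[i] = mat[i][::-1]
    return mat * scale
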