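"""TE-copy filtering and TE-derived transcription start site calls.

A TE copy is one RepeatMasker interval with a type (e.g. RLTR10, MTA_Mm),
class (LTR, LINE, SINE, DNA, ...), family (ERVK, ERVL, ERVL-MaLR, Alu, ...)
and a Smith-Waterman alignment score.  Two study rules live here:

* quality filtering — copies overlapping exons of the oocyte transcript
  annotation, or with SW score <= 500 (SINE/DNA) / <= 1000 (other classes),
  are removed;
* TE-derived promoters — a transcript's TSS is TE-derived when a TE copy on
  the same strand covers more than 51% of the 100 bp window centered on the
  TSS.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .intervals import GenomicInterval, IntervalSet

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All numeric thresholds of the pipeline, with study defaults.

    Units are bp for window sizes, TPM for expression thresholds.  The SW
    thresholds are inclusive removal bounds (a score equal to the bound is
    removed).
    """

    tss_window_bp: int = 100
    tss_te_min_coverage: float = 0.51      # strict >
    sw_min_sine_dna: int = 500             # removal bound for SINE/DNA classes
    sw_min_other: int = 1000               # removal bound for all other classes
    proximal_radius_bp: int = 1000
    promoter_upstream_bp: int = 1000
    promoter_downstream_bp: int = 100
    tts_upstream_bp: int = 100
    tts_downstream_bp: int = 1000
    expressed_tpm_min: float = 1.0
    enrichment_min_fold: float = 2.0
    enrichment_alpha: float = 0.05
    cuttag_scale_numerator: float = 10000.0
    min_count_filter: int = 2
    kmeans_k: int = 4
    # open-question switches, defaults documented in docs/methods.md
    pool_te_coverage: bool = False         # pool same-type same-strand copies at the TSS
    monoexonic_te_min_coverage: float = 0.5
    monoexonic_match_min_overlap: float = 0.5
    enrichment_bh_correction: bool = False
    enrichment_null: str = "genome"        # or "peaks": p_type over peak bp only
    ercc_method: str = "median_of_ratios"  # or "total"

    def __post_init__(self):
        for name in ("tss_window_bp", "sw_min_sine_dna", "sw_min_other",
                     "proximal_radius_bp", "promoter_upstream_bp",
                     "promoter_downstream_bp", "tts_upstream_bp",
                     "tts_downstream_bp", "expressed_tpm_min",
                     "enrichment_min_fold", "enrichment_alpha",
                     "cuttag_scale_numerator", "min_count_filter", "kmeans_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.tss_window_bp % 2:
            raise ValueError("tss_window_bp must be even (window is TSS-centered)")


SW_FILTER_CLASSES = frozenset({"SINE", "DNA"})


@dataclass(frozen=True)
class TECopy:
    """One repeat-annotation interval; the unit of enrichment analysis."""

    interval: GenomicInterval
    type: str
    te_class: str
    family: str
    sw_score: int

    def __post_init__(self):
        if self.sw_score < 0:
            raise ValueError(f"negative SW score for {self.type}")


def filter_te_copies(copies, exons: IntervalSet, config: AnalysisConfig | None = None,
                     return_reasons: bool = False):
    """Remove TE copies overlapping exons or with low SW scores.

    A copy is removed iff it overlaps the (merged, strand-agnostic) exon set
    by >= 1 bp, or its SW score is <= 500 for SINE/DNA classes, <= 1000 for
    every other class.  Input order is preserved.  Unknown class strings get
    the "other" threshold with a warning.

    With ``return_reasons`` also returns a parallel list of removal reasons
    (None for kept copies), so that reasons partition the removed set; the
    exon rule takes precedence when both apply.
    """
    config = config or AnalysisConfig()
    exons = exons if exons.merged else exons.merge()
    known_classes = SW_FILTER_CLASSES | {"LTR", "LINE", "Simple_repeat",
                                         "Low_complexity", "Satellite", "RC",
                                         "Retroposon", "rRNA", "tRNA", "snRNA",
                                         "srpRNA", "scRNA", "Unknown"}
    kept, reasons = [], []
    for copy in copies:
        if copy.te_class not in known_classes:
            log.warning("unknown TE class %r (type %s): using 'other' SW threshold",
                        copy.te_class, copy.type)
        if exons.covered_bp(copy.interval) >= 1:
            reasons.append("exon_overlap")
            continue
        bound = (config.sw_min_sine_dna if copy.te_class in SW_FILTER_CLASSES
                 else config.sw_min_other)
        if copy.sw_score <= bound:
            reasons.append("low_sw")
            continue
        kept.append(copy)
        reasons.append(None)
    if return_reasons:
        return kept, reasons
    return kept


def _tss_window(transcript, config: AnalysisConfig, chrom_length: int | None):
    half = config.tss_window_bp // 2
    tss = transcript.tss
    lo, hi = tss - half, tss + half
    truncated = False
    if lo < 0:
        lo, truncated = 0, True
    if chrom_length is not None and hi > chrom_length:
        hi, truncated = chrom_length, True
    return lo, hi, truncated


def te_at_tss(transcript, copies, config: AnalysisConfig | None = None,
              layout=None):
    """Return the TE copy covering the transcript's TSS window, if any.

    The window is the ``tss_window_bp`` region centered on the TSS,
    ``[TSS-50, TSS+50)`` by default.  Only copies on the transcript's strand
    compete; the winner must cover strictly more than ``tss_te_min_coverage``
    of the window, ties broken by larger SW score then leftmost start.
    Windows truncated at a chromosome end use the truncated length as
    denominator and are flagged.

    Returns ``(copy, coverage_fraction, truncated)`` or ``None``.

    With ``config.pool_te_coverage`` the copies of each type are pooled
    (union coverage per type) before the threshold is applied.
    """
    config = config or AnalysisConfig()
    chrom_len = layout.length(transcript.chrom) if layout is not None else None
    lo, hi, truncated = _tss_window(transcript, config, chrom_len)
    window_len = hi - lo
    if window_len <= 0:
        return None
    window = GenomicInterval(transcript.chrom, lo, hi)
    candidates = [c for c in copies
                  if c.interval.chrom == transcript.chrom
                  and c.interval.strand == transcript.strand]
    if not candidates:
        return None
    if config.pool_te_coverage:
        best, best_cov = None, -1
        for te_type in sorted({c.type for c in candidates}):
            pool = [c for c in candidates if c.type == te_type]
            cov = IntervalSet([c.interval for c in pool]).merge().covered_bp(window)
            rep = max(pool, key=lambda c: (min(c.interval.end, hi) - max(c.interval.start, lo),
                                           c.sw_score, -c.interval.start))
            if cov > best_cov:
                best, best_cov = rep, cov
        coverage = best_cov
    else:
        best, coverage = None, -1
        for c in candidates:
            cov = max(0, min(c.interval.end, hi) - max(c.interval.start, lo))
            key = (cov, c.sw_score, -c.interval.start)
            if best is None or key > (coverage, best.sw_score, -best.interval.start):
                best, coverage = c, cov
    frac = coverage / window_len
    if frac > config.tss_te_min_coverage:
        return best, frac, truncated
    return None


def te_promoter_table(transcripts, copies, config: AnalysisConfig | None = None,
                      layout=None) -> pd.DataFrame:
    """Run :func:`te_at_tss` over a transcript collection.

    One row per transcript with a TE-derived TSS; columns follow the TSV
    interface: transcript_id, gene_id, tss_chrom, tss_pos, strand, te_type,
    te_family, coverage_fraction, truncated_window.
    """
    config = config or AnalysisConfig()
    by_chrom_strand: dict[tuple[str, str], list[TECopy]] = {}
    for c in copies:
        by_chrom_strand.setdefault((c.interval.chrom, c.interval.strand), []).append(c)
    rows = []
    half = config.tss_window_bp // 2
    for t in transcripts:
        nearby = [c for c in by_chrom_strand.get((t.chrom, t.strand), ())
                  if c.interval.start < t.tss + half and c.interval.end > t.tss - half]
        hit = te_at_tss(t, nearby, config, layout=layout)
        if hit is None:
            continue
        copy, frac, truncated = hit
        rows.append({"transcript_id": t.transcript_id, "gene_id": t.gene_id,
                     "tss_chrom": t.chrom, "tss_pos": t.tss, "strand": t.strand,
                     "te_type": copy.type, "te_family": copy.family,
                     "coverage_fraction": frac, "truncated_window": truncated})
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "tss_chrom",
                                       "tss_pos", "strand", "te_type", "te_family",
                                       "coverage_fraction", "truncated_window"])


def te_family_composition(assignments) -> pd.DataFrame:
    """Family- and type-level composition of TE-TSS assignments.

    ``assignments`` is an iterable of (transcript, TECopy) pairs, each
    transcript at most once.  Returns a table with columns level
    ("family"/"type"), label, count, fraction; fractions sum to 1 within each
    level over the assigned transcripts.
    """
    pairs = list(assignments)
    seen = Counter(t.transcript_id for t, _ in pairs)
    dup = [tid for tid, n in seen.items() if n > 1]
    if dup:
        raise ValueError(f"transcripts assigned more than once: {dup[:3]}")
    if not pairs:
        return pd.DataFrame(columns=["level", "label", "count", "fraction"])
    n = len(pairs)
    rows = []
    for level, key in (("family", lambda c: c.family), ("type", lambda c: c.type)):
        counts = Counter(key(c) for _, c in pairs)
        for label in sorted(counts):
            rows.append({"level": level, "label": label,
                         "count": counts[label], "fraction": counts[label] / n})
    return pd.DataFrame(rows)
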