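"""Genomic coordinate model, interval-set algebra, and flat-file readers/writers.

All coordinates are 0-based half-open internally.  GTF (1-based closed) and
RepeatMasker ``.out`` (1-based closed) are converted at the parser boundary so
that no other module ever sees a 1-based coordinate.

The interval engine is deliberately self-contained: overlap, union coverage
and shuffling are the primitives every downstream statistic (TE filtering,
TSS coverage, peak presence, observed/expected enrichment) is built on, and
each is validated against a per-base brute-force oracle in the test suite.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A flat file violated its declared dialect."""


class ValidationError(ValueError):
    """A record violated a coordinate or layout invariant."""


# ---------------------------------------------------------------------------
# layout and interval model
# ---------------------------------------------------------------------------


class GenomeLayout:
    """Ordered chromosome name -> length (bp) table.

    The layout fixes both the coordinate bounds every interval is validated
    against and the canonical chromosome sort order used for all outputs.
    """

    def __init__(self, chrom_lengths: dict[str, int] | list[tuple[str, int]]):
        items = list(chrom_lengths.items()) if isinstance(chrom_lengths, dict) else list(chrom_lengths)
        names = [c for c, _ in items]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for name, length in items:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        self._lengths = dict(items)
        self._order = {name: i for i, name in enumerate(names)}

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def order(self, chrom: str) -> int:
        return self._order[chrom]

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeLayout({self._lengths!r})"

    @classmethod
    def read(cls, path) -> "GenomeLayout":
        """Read a two-column chromosome-sizes file (name<TAB>length)."""
        items = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
                try:
                    items.append((parts[0], int(parts[1])))
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
        return cls(items)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self._lengths.items():
                fh.write(f"{chrom}\t{length}\n")


@dataclass(frozen=True)
class GenomicInterval:
    """One stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end or negative"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def validate(self, layout: GenomeLayout) -> None:
        if self.chrom not in layout:
            raise ValidationError(f"chromosome {self.chrom!r} not in layout")
        if self.end > layout.length(self.chrom):
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds chromosome "
                f"length {layout.length(self.chrom)}"
            )


class IntervalSet:
    """A collection of :class:`GenomicInterval` with sorted per-chromosome views.

    ``merged`` is True only for sets produced by :meth:`merge`, whose intervals
    are pairwise non-overlapping (bookended runs joined) and sorted.
    """

    def __init__(self, intervals=(), layout: GenomeLayout | None = None, merged: bool = False):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.layout = layout
        self.merged = merged
        if layout is not None:
            for iv in self.intervals:
                iv.validate(layout)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sort_key(self, iv: GenomicInterval):
        order = self.layout.order(iv.chrom) if self.layout is not None else iv.chrom
        return (order, iv.start, iv.end)

    def sorted_intervals(self) -> list[GenomicInterval]:
        return sorted(self.intervals, key=self.sort_key)

    def _index(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, original indices), start-sorted."""
        if self._by_chrom is None:
            by: dict[str, list[tuple[int, int, int]]] = {}
            for i, iv in enumerate(self.intervals):
                by.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
            self._by_chrom = {}
            for chrom, rows in by.items():
                rows.sort()
                arr = np.asarray(rows, dtype=np.int64)
                self._by_chrom[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return self._by_chrom

    # -- core algebra -------------------------------------------------------

    def merge(self) -> "IntervalSet":
        """Union of coverage; bookended intervals ([a,b),[b,c)) are joined."""
        out: list[GenomicInterval] = []
        for chrom in sorted({iv.chrom for iv in self.intervals},
                            key=(self.layout.order if self.layout else str)):
            starts, ends, _ = self._index()[chrom]
            cur_s, cur_e = None, None
            for s, e in zip(starts.tolist(), ends.tolist()):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:  # overlap or bookend
                    cur_e = max(cur_e, e)
                else:
                    out.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            if cur_s is not None:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
        return IntervalSet(out, layout=self.layout, merged=True)

    def covered_bp_total(self) -> int:
        return sum(iv.length for iv in (self if self.merged else self.merge()))

    def covered_bp(self, query: GenomicInterval) -> int:
        """Bases of ``query`` covered by the union of this (merged) set."""
        if not self.merged:
            raise ValidationError("covered_bp requires a merged IntervalSet")
        idx = self._index()
        if query.chrom not in idx:
            return 0
        starts, ends, _ = idx[query.chrom]
        lo = int(np.searchsorted(ends, query.start, side="right"))
        hi = int(np.searchsorted(starts, query.end, side="left"))
        if lo >= hi:
            return 0
        s = np.maximum(starts[lo:hi], query.start)
        e = np.minimum(ends[lo:hi], query.end)
        return int(np.maximum(e - s, 0).sum())

    def contains_point(self, chrom: str, pos: int) -> bool:
        """True iff position ``pos`` lies inside the (merged) coverage."""
        if not self.merged:
            raise ValidationError("contains_point requires a merged IntervalSet")
        idx = self._index()
        if chrom not in idx:
            return False
        starts, ends, _ = idx[chrom]
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        return j >= 0 and pos < ends[j]

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`contains_point` over an array of positions."""
        if not self.merged:
            raise ValidationError("contains_points requires a merged IntervalSet")
        idx = self._index()
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in idx:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends, _ = idx[chrom]
        j = np.searchsorted(starts, positions, side="right") - 1
        ok = j >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] < ends[j[ok]]
        return out


def intersect(a: IntervalSet, b: IntervalSet, same_strand: bool = False):
    """All (interval-of-a, interval-of-b, overlap bp) pairs with overlap >= 1 bp.

    With ``same_strand`` True, pairs whose two intervals are both stranded but
    on different strands are excluded (an unstranded partner never matches a
    stranded one — conservative).
    """
    pairs = []
    b_idx = b._index()
    # ends of a start-sorted list are not themselves sorted (nesting), so the
    # left scan is bounded by the running maximum of ends instead
    cummax = {chrom: np.maximum.accumulate(ends)
              for chrom, (starts, ends, _) in b_idx.items()}
    for ia in a.sorted_intervals():
        if ia.chrom not in b_idx:
            continue
        starts, ends, orig = b_idx[ia.chrom]
        hi = int(np.searchsorted(starts, ia.end, side="left"))
        for k in range(hi - 1, -1, -1):
            if cummax[ia.chrom][k] <= ia.start:
                break
            ib = b.intervals[int(orig[k])]
            ov = min(ia.end, ib.end) - max(ia.start, ib.start)
            if ov < 1:
                continue
            if same_strand and ia.strand != ib.strand:
                continue
            if same_strand and (ia.strand == "." or ib.strand == "."):
                continue
            pairs.append((ia, ib, ov))
    return pairs


def shuffle_intervals(s: IntervalSet, layout: GenomeLayout, seed: int,
                      same_chromosome: bool = True) -> IntervalSet:
    """Random re-placement preserving each interval's length.

    New starts are uniform over valid positions.  With ``same_chromosome``
    False the target chromosome is drawn with probability proportional to its
    length among chromosomes the interval fits on.
    """
    rng = np.random.default_rng(seed)
    chroms = layout.chromosomes
    lengths = np.array([layout.length(c) for c in chroms], dtype=np.float64)
    out = []
    for iv in s.intervals:
        if same_chromosome:
            chrom = iv.chrom
            max_start = layout.length(chrom) - iv.length
            if max_start < 0:
                raise ValidationError(
                    f"interval of length {iv.length} does not fit on {chrom}")
        else:
            fits = lengths >= iv.length
            if not fits.any():
                raise ValidationError(
                    f"interval of length {iv.length} does not fit on any chromosome")
            p = np.where(fits, lengths, 0.0)
            chrom = chroms[rng.choice(len(chroms), p=p / p.sum())]
            max_start = layout.length(chrom) - iv.length
        start = int(rng.integers(0, max_start + 1))
        out.append(replace(iv, chrom=chrom, start=start, end=start + iv.length))
    return IntervalSet(out, layout=layout)


# ---------------------------------------------------------------------------
# flat-file I/O
# ---------------------------------------------------------------------------


def read_bed(path, layout: GenomeLayout) -> IntervalSet:
    """Read BED3-BED6 (0-based half-open); strand from column 6 when present."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = None
            if len(cols) > 4 and cols[4] != ".":
                try:
                    score = float(cols[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score {cols[4]!r}") from None
            strand = cols[5] if len(cols) > 5 else "."
            if strand not in STRANDS:
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            iv = GenomicInterval(cols[0], start, end, strand, score, name)
            try:
                iv.validate(layout)
            except ValidationError as err:
                raise ValidationError(f"{path}:{lineno}: {err}") from None
            out.append(iv)
    return IntervalSet(out, layout=layout)


def write_bed(s: IntervalSet, path) -> None:
    """Write BED6 when any interval carries strand/score/name, else BED3."""
    rich = any(iv.strand != "." or iv.score is not None or iv.name is not None
               for iv in s.intervals)
    with open(path, "w") as fh:
        for iv in s.sorted_intervals():
            if rich:
                score = "0" if iv.score is None else format(iv.score, "g")
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def _gtf_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path, layout: GenomeLayout):
    """Read exon features from a GTF file into transcript models.

    GTF is 1-based closed; exon coordinates are converted to 0-based half-open
    here.  Exons are grouped by ``transcript_id``, sorted, and checked for a
    single chromosome/strand per transcript.

    Returns a list of :class:`ervatac.transcripts.TranscriptModel` (imported
    lazily to keep module layering acyclic).
    """
    from .transcripts import TranscriptModel

    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            if cols[2] != "exon":
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = cols[6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: exon strand must be + or -")
            attrs = _gtf_attributes(cols[8])
            if "transcript_id" not in attrs:
                raise ParseError(f"{path}:{lineno}: exon lacks transcript_id attribute")
            tid = attrs["transcript_id"]
            iv = GenomicInterval(cols[0], start1 - 1, end1, strand)
            try:
                iv.validate(layout)
            except ValidationError as err:
                raise ValidationError(f"{path}:{lineno}: {err}") from None
            if tid not in exons:
                order.append(tid)
            exons.setdefault(tid, []).append(iv)
            genes.setdefault(tid, attrs.get("gene_id", tid))
    out = []
    for tid in order:
        evs = sorted(exons[tid], key=lambda iv: iv.start)
        if len({e.chrom for e in evs}) > 1:
            raise ValidationError(f"transcript {tid}: exons on multiple chromosomes")
        if len({e.strand for e in evs}) > 1:
            raise ValidationError(f"transcript {tid}: exons on mixed strands")
        for prev, nxt in zip(evs, evs[1:]):
            if nxt.start < prev.end:
                raise ValidationError(f"transcript {tid}: overlapping exons")
        out.append(TranscriptModel(
            transcript_id=tid, gene_id=genes[tid], chrom=evs[0].chrom,
            strand=evs[0].strand, exons=tuple((e.start, e.end) for e in evs)))
    return out


def read_repeatmasker_out(path, layout: GenomeLayout):
    """Read a RepeatMasker ``.out`` file into TE copies.

    Dialect: 3 header lines; whitespace-separated body; column 1 = SW score,
    columns 5-7 = query chromosome, begin (1-based), end (inclusive), column
    9 = strand ("+" or "C" for complement), column 10 = repeat name (type),
    column 11 = class/family as e.g. ``LTR/ERVK``.
    """
    from .te_annotation import TECopy

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3:
                continue
            if not line.strip():
                continue
            cols = line.split()
            if len(cols) < 11:
                raise ParseError(f"{path}:{lineno}: expected >=11 whitespace-separated columns")
            try:
                sw = int(cols[0])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric SW score {cols[0]!r}") from None
            chrom = cols[4]
            try:
                begin1, end1 = int(cols[5]), int(cols[6])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            strand_tok = cols[8]
            if strand_tok == "C":
                strand = "-"
            elif strand_tok in ("+", "-"):
                strand = "+" if strand_tok == "+" else "-"
            else:
                raise ParseError(f"{path}:{lineno}: invalid strand token {strand_tok!r}")
            te_type = cols[9]
            classfam = cols[10]
            te_class, _, family = classfam.partition("/")
            iv = GenomicInterval(chrom, begin1 - 1, end1, strand)
            try:
                iv.validate(layout)
            except ValidationError as err:
                raise ValidationError(f"{path}:{lineno}: {err}") from None
            out.append(TECopy(interval=iv, type=te_type, te_class=te_class,
                              family=family or te_class, sw_score=sw))
    return out


def write_repeatmasker_out(copies, path) -> None:
    """Write TE copies in the minimal RepeatMasker ``.out`` dialect we read."""
    header = (
        "   SW  perc perc perc  query      position in query           matching"
        "       repeat              position in  repeat\n"
        "score  div. del. ins.  sequence    begin     end    (left)    repeat"
        "         class/family         begin  end (left)   ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, c in enumerate(copies, 1):
            iv = c.interval
            strand = "C" if iv.strand == "-" else "+"
            classfam = f"{c.te_class}/{c.family}" if c.family != c.te_class else c.te_class
            fh.write(
                f"{c.sw_score} 0.0 0.0 0.0 {iv.chrom} {iv.start + 1} {iv.end} (0) "
                f"{strand} {c.type} {classfam} 1 {iv.length} (0) {i}\n"
            )
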