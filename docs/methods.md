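# Methods

This note documents the models and procedures implemented in `ervatac`, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Coordinate model

All internal coordinates are 0-based half-open on a fixed `GenomeLayout`
(ordered chromosome → length table). The two 1-based-closed dialects —
GTF and RepeatMasker `.out` — are converted at the parser boundary and
nowhere else; RepeatMasker's complement strand token `C` maps to `−`.
`merge()` joins bookended intervals (`[a,b) + [b,c) → [a,c)`), i.e. union
of coverage, which is the semantics the coverage fractions below need.
All outputs are sorted by (layout chromosome order, start, end) so reruns
diff cleanly.

## TE annotation and TE-derived promoters

A TE copy carries type (e.g. RLTR10, MTA_Mm), class (LTR, LINE, SINE,
DNA, …), family (ERVK, ERVL, ERVL-MaLR, …) and a Smith–Waterman alignment
score. Two distinct TE sets exist in the pipeline and must not be
confused:

* the **distal/enrichment set** — copies overlapping any exon of the
  transcript annotation by ≥ 1 bp are removed, as are low-quality copies
  with SW ≤ 500 (SINE and DNA classes) or SW ≤ 1000 (all other classes;
  both bounds inclusive). Unknown class strings fall back to the stricter
  1000 bound with a warning.
* the **promoter-call set** — the full unfiltered annotation. A TE that
  covers a TSS necessarily overlaps the first exon, so the exon-filtered
  set cannot be used to call TE-derived promoters; the exon filter exists
  to prepare the distal analyses only.

A transcript TSS is TE-derived when a copy on the **same strand** covers
strictly more than 51% of the 100 bp window centred on the TSS,
`[TSS−50, TSS+50)`. "Surrounding" is read as symmetric; the window size is
configurable but must stay even. Coverage is evaluated per copy (the study
assigns one TE per TSS in its composition charts); pooling same-type
copies into a union is available behind `pool_te_coverage` but off by
default. Ties are broken by higher SW score, then leftmost start. Windows
truncated at a chromosome end use the truncated length as denominator and
are flagged — with a 100 bp window this is a theoretical corner, but the
flag keeps the behaviour explicit rather than silent.

## Transcript novelty

gffcompare's ~15 class codes are collapsed to the three levels the
downstream statistics need:

* `known_transcript` — identical intron chain to a same-strand reference
  transcript (multi-exonic), or ≥ 50% **reciprocal** exonic overlap with a
  same-strand mono-exonic reference transcript (mono-exonic);
* `novel_isoform_of_known_gene` — ≥ 1 bp same-strand exonic overlap with
  some reference transcript, without a match above;
* `novel_gene_transcript` — no same-strand exonic overlap at all.

Antisense overlap is never a match. The 50% reciprocal rule for
mono-exonic matching is a concrete stand-in for gffcompare's mono-exonic
handling and is configurable. A gene is novel iff *all* of its transcripts
are `novel_gene_transcript`; known genes with ≥ 1 novel-isoform call are
flagged separately. Before classification, mono-exonic transcripts with
≥ 50% of their exonic length covered by same-strand TE copies are removed
("transcribed from known TE"); the paper gives no number for this
coverage, so 0.5 is a configurable default, and the rule never touches
multi-exonic transcripts.

## Expression

**TPM** is length-normalized within sample; spike-in rows are excluded
from the denominator (their TPM-scale values are reported separately), so
each TPM column sums to 10⁶ over genes.

**Low-count filter**: keep a feature iff some sample has ≥ 2 counts.

**Per-cell normalization.** ERCC-like spike-ins enter at a fixed amount
per cell, so their count variation across samples estimates library scale.
Size factors are DESeq-style median-of-ratios restricted to spike-in rows
positive in every sample (≥ 3 required, otherwise the error message points
to the total-spike-in fallback, `ercc_method="total"`), rescaled to
geometric mean 1; per-cell expression = count / factor. The study computed
factors with edgeR and transformed with voom; median-of-ratios targets the
same estimand (per-cell scaling) and is self-contained and directly
testable against planted fold changes. The CUT&Tag analogue is the scalar
`10000 / spike-in reads`.

**Expressed genes**: max over stage means (arithmetic mean of replicates;
per-replicate thresholding is the other defensible reading, the paper does
not say) strictly greater than 1 TPM; the complement is "Others".

**Stage groups**: k-means (k = 4, k-means++, 50 restarts, fixed seed) on
per-gene z-scored stage means. Genes are sorted by id before fitting so
input order cannot change labels; constant rows are held out and assigned
to the nearest centroid afterwards. Clusters are renumbered canonically by
the expression-weighted mean stage index of each centroid — weights are
the centroid shifted to be non-negative (`c − min c`), needed because
z-scored centroids have negative entries — so Group 1 always peaks
earliest and the numbering is reproducible across seeds.

## Chromatin dynamics

Peaks are categorized by their **centre** (`⌊(start+end)/2⌋`) with priority
promoter > TTS > exon > intron > intergenic. The promoter window is
−1000…+100 bp of the TSS in transcription direction (half-open at the
downstream edge), the TTS window −100…+1000 bp of the termination site,
both mirrored on the minus strand. The nearest gene minimizes
|centre − TSS|, ties to the smaller gene id; reported distances are signed
in the gene's direction.

The proximal/distal split is centre within ±1 kb of any TSS, boundary
**inclusive** (the paper does not state the boundary convention; it is
fixed and documented here). Centre-based conventions make the analytic
overlap expectation exactly the bp fraction and match annotatePeaks-style
distance conventions.

**Presence classes.** The region universe is the merge of all stage peaks;
a region is present in a stage iff it overlaps a stage peak by ≥ 1 bp
(any-overlap, matching BEDTools-intersect phrasing). With three stages the
seven non-empty patterns map to classes with three anchored numbers —
(−,+,+) → 3, (−,−,+) → 4, (+,+,+) → 5 — and the four unanchored patterns
(+,−,−), (+,+,−), (+,−,+), (−,+,−) take 1, 2, 6, 7 by fixed convention.
Any other stage count yields pattern bit-strings instead of numbers.
Presence/absence (not signal-level clustering) is implemented because the
source figure's legend is written in +/− notation.

**Primed accessible chromatin** = NGO peaks with ≥ 1 bp overlap with any
GO peak, reported at NGO coordinates.

**Observed vs expected TE overlap.** Observed = fraction of peak centres
inside merged TE coverage. The analytic null is genome-uniform placement,
expectation = TE bp / genome bp. The permutation null re-places each peak
(length preserved, start uniform over valid positions) **across
chromosomes with probability proportional to length** — a same-chromosome
shuffle is not comparable to the genome-fraction expectation whenever
per-chromosome peak density differs — and reports the Monte-Carlo mean and
standard error. Residual discrepancy of order peak-length/chromosome-length
(centres cannot fall within half a peak length of chromosome ends) is
negligible at the scales used (≤ 400 bp peaks on ≥ 1 Mb chromosomes).

**signal_over_regions** bins flank-expanded regions into n equal bins and
counts fragments overlapping each bin by ≥ 1 bp, times an external scale
factor (e.g. the CUT&Tag spike-in scalar); minus-strand rows are reversed
so bin 0 is 5′.

## ERV enrichment

For type *T*: a fragment counts for *T* iff its centre lies inside an
accessible peak **and** inside a copy of *T*; `n_total` is all in-peak
fragments; a fragment maps to at most one type (overlapping copies resolve
by higher SW score — the mm10 annotation is non-overlapping, so this is a
robustness measure). With *p*<sub>T</sub> = genomic bp fraction of the
type's union coverage,

expected = n·p_T, fold = observed/expected (0 when expected is 0), and
*P* = Pr(X ≥ observed) for X ~ Binomial(n, p_T), computed through the
regularized-incomplete-beta identity (exact to floating precision; the
test suite pins it to direct pmf summation at 1e−12 for n ≤ 50). A type is
enriched iff fold ≥ 2 **and** *P* < 0.05. No multiple-testing correction
by default, matching the two-gate rule as printed; Benjamini–Hochberg is
available behind `enrichment_bh_correction`. The null universe is the
genome ("expected genomic prevalence"); a peaks-only universe
(p_T over peak bp) sits behind `enrichment_null="peaks"` because the
study's exact universe is ambiguous.

Calibration is checked two ways. The type-I study draws per-type observed
counts as a multinomial over (types, background) — exactly the
distribution of uniformly placed fragment centres over non-overlapping
copies with fully accessible chromatin — at n = 500,000 per replicate,
500 replicates, 20 types with p_T ≈ 0.012 from a planted annotation; the
p < 0.05 call rate must land in the exact binomial 95% interval around
0.05. The large n keeps the discreteness bias of the exact tail
(≈ φ(1.64)/(2σ) ≈ 0.0007 here) well inside that interval; at small n the
exact test is visibly conservative and the check would not be meaningful.
The power study plants a 4× fragment density (observed ~ Binomial(n, q),
q = 4p/(1+3p)) at n = 10,000 and requires the two-gate call in ≥ 95% of
200 replicates. The geometric counting path itself is validated separately
against a brute-force triple-loop oracle.

**Neighbor-gene comparisons** take two region-derived gene groups (each
gene once per group), and return per-group stage-expression vectors with
two-sided Mann–Whitney U and Welch t p-values, plus sorted values for
empirical CDFs.

## Synthetic-data generator

One global seed is split (`numpy.random.SeedSequence.spawn`) into fixed
per-component child seeds — genome, TE, transcripts, peaks, fragments,
counts — so changing one component's model never perturbs another's draw,
and every artifact is a pure function of the `ScenarioSpec`.

The default "small" scenario: 2 × 1 Mb chromosomes; 24 TE types (20 ERV
across ERVK/ERVL/ERVL-MaLR plus LINE/SINE/DNA background), 30 copies per
type, lengths 150–500 bp, SW 1200–8000 (above the filter bounds unless
low-SW planting is requested); 300 gene models (20% novel genes, 10% novel
isoforms, 30% TE-derived promoters); 600 peak-universe regions of
200–400 bp with a fixed mixture over the seven presence classes; 20,000
fragments per stage with RLTR10 and MTA_Mm planted at 4× density; and a
4-stage × 3-replicate count matrix over 2,000 genes (log-uniform baselines
50–500, four archetype stage profiles with 5× peaks, NB dispersion 0.1,
log-normal library scales σ = 0.3) with 92 spike-in species — the species
count of the ERCC spike-in mix — at log-uniform per-cell abundances
20–2000. It generates in under a second.

Planting is exact (`round(fraction · n)` items of each kind), so noiseless
recoveries can be asserted as equalities. TE-promoter genes take their TSS
60 bp inside an ERV copy of ≥ 120 bp on the copy's strand, so the copy
covers the whole TSS window; each planted promoter is re-verified with the
caller at generation time. All other gene bodies are laid into TE-free
gaps with random spacing, so their TSS windows are TE-free and false
positives cannot arise silently. Peak-universe regions avoid all TE
footprints by ≥ 2 bp so that the TE-accessibility peaks (every copy of a
planted-enriched type, present at all stages) never merge with mixture
regions and pattern truth survives merging. GO peaks are a planted
fraction (0.6) of NGO peaks at identical coordinates plus GO-specific
regions, making primed-chromatin truth exact. Fragments come from a
two-component model: uniform background plus, inside each enriched type's
copies, extra mass so total density is fold × background.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequence content and mappability (no reads, no
multimapping, though multimapping is the central practical difficulty of
real TE quantification), TE insertion-age structure and nested/fragmented
copies, peak-caller boundary noise (planted peaks are exact intervals),
overdispersion structure beyond a single NB dispersion, batch effects, and
spike-in pipetting variation beyond the library-scale log-normal. Tests on
this generator validate the *statistics and their calibration*, not
upstream data quality.

## Problem sizes and runtime

The acceptance script regenerates everything from a seed and runs in
~15 s on one CPU: 100 oracle instances on a 100 kb genome; the binomial
tail over all n ≤ 50; the type-I study at 500 × 500,000; power at
200 × 10,000; fold recovery over 400 genes × 12 samples; TE-promoter
recovery over 5,000 transcripts on an 8 Mb genome; novelty over 2,000
genes; 1,000 shuffles of the NGO peak set; and the full small scenario
end-to-end. These sizes were chosen as the smallest at which each check's
sampling error is clearly inside its tolerance.

## Known limitations

* `n_total` in the enrichment test is genome-wide in-peak fragments;
  whether the study computed it per family is not stated (a per-family
  variant would change expected counts proportionally).
* Fragment counting uses centres; per-bp coverage weighting ("read
  counts" is ambiguous) would weight long fragments more.
* The presence-class numbering of the four unanchored patterns is a
  convention of this package; only Classes 3, 4, 5 are anchored to the
  source.
* The exact binomial tail is conservative at small expected counts; calls
  on types with tiny genomic fractions lose power accordingly.
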