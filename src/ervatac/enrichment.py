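"""Per-ERV-type observed/expected read enrichment in accessible chromatin.

For each ERV (or any TE) type T the statistic compares the number of
sequenced fragments whose center falls inside an accessible-chromatin peak
AND inside a copy of T (observed) with the count expected if fragments were
uniform over the genome: expected = n_total * p_T, where p_T is the genomic
bp fraction of T after filtering and n_total is the number of in-peak
fragments.  A type is called enriched when observed/expected >= 2 and the
one-sided upper binomial tail P(X >= observed), X ~ Bin(n_total, p_T), is
below 0.05 — the study's two-gate rule, no multiple-testing correction by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeLayout, GenomicInterval, IntervalSet
from .te_annotation import AnalysisConfig, TECopy


@dataclass(frozen=True)
class EnrichmentResult:
    erv_type: str
    family: str
    observed_reads: int
    expected_reads: float
    fold: float
    p_value: float
    enriched: bool


def binomial_tail(observed: int, n_total: int, p: float) -> float:
    """Exact one-sided upper tail P(X >= observed), X ~ Binomial(n_total, p).

    Uses the regularized-incomplete-beta identity (scipy's binom.sf), exact
    to floating precision for the n used here.
    """
    if observed <= 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, n_total, p))


def binomial_enrichment(observed: int, n_total: int, p_type: float,
                        config: AnalysisConfig | None = None,
                        erv_type: str = "", family: str = "") -> EnrichmentResult:
    """Observed/expected fold and binomial tail for one type.

    ``p_type`` is the genomic bp fraction of the type; expected =
    n_total * p_type; fold = observed/expected (0 when expected is 0);
    enriched iff fold >= config fold gate AND p < config alpha.
    """
    config = config or AnalysisConfig()
    if not (0 < p_type < 1):
        raise ValueError(f"p_type must be in (0, 1), got {p_type}")
    if not (0 <= observed <= n_total):
        raise ValueError("need 0 <= observed <= n_total")
    expected = n_total * p_type
    fold = observed / expected if expected > 0 else 0.0
    p_value = binomial_tail(observed, n_total, p_type)
    enriched = (fold >= config.enrichment_min_fold) and (p_value < config.enrichment_alpha)
    return EnrichmentResult(erv_type, family, observed, expected, fold, p_value, enriched)


def reads_per_erv_type(fragments: IntervalSet, peaks: IntervalSet, te):
    """Observed in-peak fragment counts per TE type.

    A fragment is counted for type T iff its center lies inside a peak and
    inside a copy of T; in-peak fragments outside every copy contribute only
    to ``n_total``.  A fragment maps to at most one type — when copies
    overlap, the copy with the larger SW score wins.

    Returns ``(counts: dict type -> int, n_total: int)``.
    """
    import warnings

    if len(peaks) == 0:
        warnings.warn("empty peak set: all observed counts are zero")
        types = sorted({c.type for c in te})
        return {t: 0 for t in types}, 0
    peaks_merged = peaks if peaks.merged else peaks.merge()
    # per-chromosome sorted copy table (start, end, sw, type index)
    types = sorted({c.type for c in te})
    type_idx = {t: i for i, t in enumerate(types)}
    by_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for c in te:
        by_chrom.setdefault(c.interval.chrom, []).append(
            (c.interval.start, c.interval.end, c.sw_score, type_idx[c.type]))
    idx = {}
    for chrom, rows in by_chrom.items():
        rows.sort()
        arr = np.asarray(rows, dtype=np.int64)
        idx[chrom] = arr
    counts = np.zeros(len(types), dtype=np.int64)
    n_total = 0
    frag_by_chrom: dict[str, list[int]] = {}
    for f in fragments:
        frag_by_chrom.setdefault(f.chrom, []).append(f.center)
    for chrom, centers in frag_by_chrom.items():
        centers = np.asarray(centers, dtype=np.int64)
        in_peak = peaks_merged.contains_points(chrom, centers)
        n_total += int(in_peak.sum())
        if chrom not in idx:
            continue
        arr = idx[chrom]
        starts, ends = arr[:, 0], arr[:, 1]
        pos = centers[in_peak]
        disjoint = bool((starts[1:] >= ends[:-1]).all()) if len(arr) > 1 else True
        if disjoint:
            # at most one covering copy: the last with start <= pos
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = (j >= 0)
            ok[ok] = pos[ok] < ends[j[ok]]
            np.add.at(counts, arr[j[ok], 3], 1)
        else:
            # running max of ends bounds the leftward scan exactly
            cum_end = np.maximum.accumulate(ends)
            for p in pos.tolist():
                j = int(np.searchsorted(starts, p, side="right"))
                best = None  # (sw score, type index)
                k = j - 1
                while k >= 0 and cum_end[k] > p:
                    if arr[k, 1] > p:  # start <= p holds for all k < j
                        cand = (int(arr[k, 2]), int(arr[k, 3]))
                        if best is None or cand[0] > best[0]:
                            best = cand
                    k -= 1
                if best is not None:
                    counts[best[1]] += 1
    return {t: int(counts[type_idx[t]]) for t in types}, n_total


def genomic_type_fractions(te, layout: GenomeLayout) -> pd.Series:
    """Genomic bp fraction per TE type (union coverage per type)."""
    by_type: dict[str, list[GenomicInterval]] = {}
    for c in te:
        by_type.setdefault(c.type, []).append(c.interval)
    total = layout.total_bp
    return pd.Series({t: IntervalSet(ivs).merge().covered_bp_total() / total
                      for t, ivs in sorted(by_type.items())})


def erv_enrichment_table(fragments: IntervalSet, peaks: IntervalSet, te,
                         layout: GenomeLayout,
                         config: AnalysisConfig | None = None) -> pd.DataFrame:
    """One EnrichmentResult row per TE type in the annotation.

    With ``config.enrichment_null == "peaks"`` the null universe is peak bp
    rather than the whole genome: p_T = (type bp inside peaks) / (peak bp).
    With ``config.enrichment_bh_correction`` a Benjamini-Hochberg adjusted
    p-value column is added and used for the significance gate.
    """
    config = config or AnalysisConfig()
    counts, n_total = reads_per_erv_type(fragments, peaks, te)
    family_of = {}
    for c in te:
        family_of.setdefault(c.type, c.family)
    if config.enrichment_null == "peaks":
        peaks_merged = peaks if peaks.merged else peaks.merge()
        peak_bp = peaks_merged.covered_bp_total()
        p_frac = {}
        for t in counts:
            ivs = [c.interval for c in te if c.type == t]
            inside = sum(peaks_merged.covered_bp(iv)
                         for iv in IntervalSet(ivs).merge())
            p_frac[t] = inside / peak_bp if peak_bp else 0.0
        p_frac = pd.Series(p_frac)
    else:
        p_frac = genomic_type_fractions(te, layout)
    rows = []
    for t in sorted(counts):
        p = float(p_frac[t])
        if not (0 < p < 1):
            rows.append({"erv_type": t, "family": family_of[t],
                         "observed": counts[t], "expected": n_total * p,
                         "fold": 0.0, "p_value": 1.0, "enriched": False})
            continue
        r = binomial_enrichment(counts[t], n_total, p, config, t, family_of[t])
        rows.append({"erv_type": t, "family": r.family, "observed": r.observed_reads,
                     "expected": r.expected_reads, "fold": r.fold,
                     "p_value": r.p_value, "enriched": r.enriched})
    df = pd.DataFrame(rows)
    if config.enrichment_bh_correction and len(df):
        from statsmodels.stats.multitest import multipletests

        _, padj, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["p_adj"] = padj
        df["enriched"] = (df["fold"] >= config.enrichment_min_fold) & \
                         (df["p_adj"] < config.enrichment_alpha)
    return df


def select_accessible_erv_loci(te, peaks_by_stage, tss_list,
                               config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Accessible (>= 1 bp peak overlap) TE copies per stage, proximal/distal
    labeled by copy center vs TSS +-1 kb."""
    config = config or AnalysisConfig()
    merged = {st: peaks_by_stage.peaks[st].merge() for st in peaks_by_stage.stages}
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in tss_list:
        by_chrom.setdefault(chrom, []).append(pos)
    tss_sorted = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}
    rows = []
    for c in te:
        center = c.interval.center
        tss = tss_sorted.get(c.interval.chrom)
        if tss is not None and len(tss):
            j = int(np.searchsorted(tss, center))
            d = min(abs(center - int(tss[k])) for k in (j - 1, j) if 0 <= k < len(tss))
            proximity = "proximal" if d <= config.proximal_radius_bp else "distal"
        else:
            proximity = "distal"
        for st in peaks_by_stage.stages:
            if merged[st].covered_bp(c.interval) >= 1:
                rows.append({"stage": st, "erv_type": c.type, "family": c.family,
                             "chrom": c.interval.chrom, "start": c.interval.start,
                             "end": c.interval.end, "proximity": proximity})
    return pd.DataFrame(rows, columns=["stage", "erv_type", "family", "chrom",
                                       "start", "end", "proximity"])


def type_i_error_study(p_types, n_total: int, n_replicates: int, seed: int,
                       alpha: float = 0.05) -> dict:
    """False-positive rate of the binomial tail under the uniform null.

    For fragments placed uniformly on the genome with non-overlapping TE
    copies, the per-type observed counts are jointly multinomial with cell
    probabilities ``p_types`` (and a background cell); the study draws those
    counts directly and applies :func:`binomial_tail` to each, counting
    ``p < alpha`` calls (the p-value gate alone — no fold gate).

    Returns the call rate, the number of calls and of trials.
    """
    p = np.asarray(list(p_types), dtype=float)
    if (p <= 0).any() or p.sum() >= 1:
        raise ValueError("p_types must be positive and sum to < 1")
    rng = np.random.default_rng(seed)
    cells = np.append(p, 1.0 - p.sum())
    calls = 0
    for _ in range(n_replicates):
        obs = rng.multinomial(n_total, cells)[:-1]
        for o, pt in zip(obs, p):
            if binomial_tail(int(o), n_total, float(pt)) < alpha:
                calls += 1
    trials = n_replicates * len(p)
    return {"rate": calls / trials, "calls": calls, "trials": trials}


def power_study(p_type: float, density_fold: float, n_total: int,
                n_replicates: int, seed: int,
                config: AnalysisConfig | None = None) -> dict:
    """Recovery rate of a planted enrichment under the two-gate rule.

    Fragment density inside the type's copies is ``density_fold`` times
    background, so a fragment lands in the type with probability
    q = fold * p / (1 + (fold - 1) * p); observed ~ Binomial(n_total, q).
    Each replicate is called enriched iff fold >= 2 and binomial p < 0.05
    (config gates).
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    q = density_fold * p_type / (1.0 + (density_fold - 1.0) * p_type)
    hits = 0
    for _ in range(n_replicates):
        obs = int(rng.binomial(n_total, q))
        r = binomial_enrichment(obs, n_total, p_type, config)
        hits += r.enriched
    return {"rate": hits / n_replicates, "replicates": n_replicates,
            "expected_fold": q / p_type}


def neighbor_gene_compare(genes_a, genes_b, expression, stage: str) -> dict:
    """Compare stage expression of two gene groups (e.g. genes adjacent to
    distal accessible TEs vs distal non-TE accessible regions).

    ``genes_a``/``genes_b`` are gene-id iterables (each gene counted once per
    group); ``expression`` an ExpressionMatrix.  Returns the per-group value
    vectors, empirical CDF supports, Mann-Whitney U two-sided p and Welch t
    two-sided p.
    """
    means = expression.stage_means()
    if stage not in means.columns:
        raise ValueError(f"stage {stage!r} not in expression matrix")
    va = means.loc[means.index.intersection(pd.Index(set(genes_a))), stage].to_numpy()
    vb = means.loc[means.index.intersection(pd.Index(set(genes_b))), stage].to_numpy()
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("each group needs at least 2 genes with expression values")
    u = stats.mannwhitneyu(va, vb, alternative="two-sided")
    t = stats.ttest_ind(va, vb, equal_var=False)
    return {
        "values_a": np.sort(va), "values_b": np.sort(vb),
        "n_a": len(va), "n_b": len(vb),
        "median_a": float(np.median(va)), "median_b": float(np.median(vb)),
        "ranksum_p": float(u.pvalue), "welch_t_p": float(t.pvalue),
    }
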