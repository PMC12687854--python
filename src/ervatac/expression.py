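"""Expression quantification, spike-in normalization, filtering, and grouping.

Per-cell comparability across developmental stages is obtained from ERCC-like
spike-ins added at a fixed amount per cell: because their true abundance per
cell is constant, sample-to-sample variation of spike-in counts measures
library scale, and dividing gene counts by a spike-in-derived size factor
yields per-cell expression.  Size factors use the median-of-ratios estimator
restricted to spike-in rows (DESeq-style: ratio of each spike-in's count to
its across-sample geometric mean, median over spike-ins), rescaled to
geometric mean 1.

TPM is the usual length-normalized within-sample unit; spike-in rows are
excluded from the TPM denominator so library composition of the spike-in mix
cannot distort gene TPMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances_argmin


@dataclass
class CountMatrix:
    """Raw feature-by-sample integer counts with spike-in flags.

    ``counts``: DataFrame, rows = feature ids, columns = sample ids.
    ``lengths``: per-feature length in bp (sum of merged exon lengths).
    ``is_spikein``: per-feature boolean.
    ``stages``: per-sample stage label; ``replicates``: per-sample index.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    is_spikein: pd.Series
    stages: pd.Series
    replicates: pd.Series | None = None

    def __post_init__(self):
        self.lengths = self.lengths.reindex(self.counts.index)
        self.is_spikein = self.is_spikein.reindex(self.counts.index).fillna(False).astype(bool)
        self.stages = self.stages.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"non-positive length for feature {bad}")

    @property
    def gene_counts(self) -> pd.DataFrame:
        return self.counts.loc[~self.is_spikein]

    @property
    def spikein_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.is_spikein]

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.insert(1, "is_spikein", self.is_spikein.astype(int))
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def read_tsv(cls, path, stages: pd.Series | None = None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        lengths = df.pop("length")
        spike = df.pop("is_spikein").astype(bool)
        if stages is None:
            # sample ids of the form <stage>_rep<k>
            stages = pd.Series({c: c.rsplit("_", 1)[0] for c in df.columns})
        return cls(df.astype(np.int64), lengths, spike, stages)


@dataclass
class ExpressionMatrix:
    """Normalized feature-by-sample values; ``unit`` is 'TPM' or 'per_cell'."""

    values: pd.DataFrame
    unit: str
    stages: pd.Series
    spikein_values: pd.DataFrame | None = None

    def stage_means(self) -> pd.DataFrame:
        """Feature-by-stage arithmetic means of replicates, in stage order."""
        ordered = list(dict.fromkeys(self.stages))
        return self.values.T.groupby(self.stages).mean().T[ordered]


def compute_tpm(m: CountMatrix) -> ExpressionMatrix:
    """Transcripts-per-million; spike-ins excluded from the denominator.

    TPM_ij = (c_ij / len_i) / sum_k non-spike (c_kj / len_k) * 1e6.  Spike-in
    rows are scaled by the same per-sample denominator and reported in
    ``spikein_values``.
    """
    rate = m.counts.div(m.lengths, axis=0)
    denom = rate.loc[~m.is_spikein].sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has all-zero non-spike-in counts")
    tpm = rate.div(denom, axis=1) * 1e6
    return ExpressionMatrix(values=tpm.loc[~m.is_spikein], unit="TPM",
                            stages=m.stages,
                            spikein_values=tpm.loc[m.is_spikein])


def low_count_filter(m: CountMatrix, min_count: int = 2) -> CountMatrix:
    """Keep features with at least ``min_count`` counts in some sample."""
    keep = (m.counts.max(axis=1) >= min_count) | m.is_spikein
    return CountMatrix(m.counts.loc[keep], m.lengths.loc[keep],
                       m.is_spikein.loc[keep], m.stages, m.replicates)


def ercc_size_factors(m: CountMatrix, method: str = "median_of_ratios") -> pd.Series:
    """Per-sample size factors from spike-in rows, geometric mean 1.

    ``median_of_ratios``: factor_j = median over spike-ins i (positive in all
    samples) of c_ij / geomean_i(c_i.).  ``total``: factor_j proportional to
    the spike-in column sum.  Per-cell value = count / factor.
    """
    spikes = m.spikein_counts
    if method == "total":
        totals = spikes.sum(axis=0).astype(float)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise ValueError(f"sample {bad!r} has zero spike-in reads")
        factors = totals
    elif method == "median_of_ratios":
        usable = spikes.loc[(spikes > 0).all(axis=1)]
        if len(usable) < 3:
            raise ValueError(
                "fewer than 3 spike-in rows positive in all samples; "
                "fall back to method='total' (total-spike-in scaling)")
        logc = np.log(usable.to_numpy(dtype=float))
        log_geomean = logc.mean(axis=1, keepdims=True)
        ratios = np.exp(logc - log_geomean)
        factors = pd.Series(np.median(ratios, axis=0), index=spikes.columns)
    else:
        raise ValueError(f"unknown size-factor method {method!r}")
    factors = factors / np.exp(np.log(factors).mean())
    return factors


def normalize_per_cell(m: CountMatrix, factors: pd.Series | None = None,
                       method: str = "median_of_ratios") -> ExpressionMatrix:
    """Divide counts by spike-in size factors (per-cell unit)."""
    if factors is None:
        factors = ercc_size_factors(m, method=method)
    values = m.counts.div(factors, axis=1)
    return ExpressionMatrix(values=values.loc[~m.is_spikein], unit="per_cell",
                            stages=m.stages,
                            spikein_values=values.loc[m.is_spikein])


def cuttag_scale_factor(spikein_reads: int, numerator: float = 10000.0) -> float:
    """Exogenous spike-in scale factor: numerator / spike-in read count."""
    if spikein_reads <= 0:
        raise ValueError("spike-in read count must be positive")
    return numerator / spikein_reads


def expressed_filter(e: ExpressionMatrix, stages=None, tpm_min: float = 1.0) -> pd.Series:
    """Expressed iff the max of stage-mean TPM strictly exceeds ``tpm_min``.

    Returns a boolean Series over features (True = expressed, False =
    "Others").  ``stages`` lists the required stage labels; a stage absent
    from the matrix raises.
    """
    means = e.stage_means()
    if stages is not None:
        missing = [s for s in stages if s not in means.columns]
        if missing:
            raise ValueError(f"missing stage(s) {missing} in expression matrix")
        means = means[list(stages)]
    return means.max(axis=1) > tpm_min


def group_genes_kmeans(e: ExpressionMatrix, k: int = 4, seed: int = 0) -> pd.Series:
    """k-means grouping of expressed genes on z-scored stage means.

    Each gene's stage means are standardized to zero mean / unit variance;
    constant rows (zero variance) are held out of the fit and assigned to the
    nearest centroid afterwards.  k-means++ with 50 restarts at a fixed seed.
    Clusters are relabeled canonically as Groups 1..k by ascending
    expression-weighted mean stage index of the centroid (weights = centroid
    shifted to be non-negative), so Group 1 peaks earliest.
    """
    means = e.stage_means()
    if len(means) < k:
        raise ValueError(f"need at least k={k} genes, got {len(means)}")
    means = means.sort_index()  # label assignment independent of input order
    x = means.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    const = (sd == 0).ravel()
    z = np.zeros_like(x)
    np.divide(x - mu, sd, out=z, where=sd > 0)
    fit_rows = z[~const]
    if len(fit_rows) < k:
        raise ValueError("fewer than k non-constant genes")
    km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=seed)
    labels_fit = km.fit_predict(fit_rows)
    labels = np.empty(len(z), dtype=int)
    labels[~const] = labels_fit
    if const.any():
        labels[const] = pairwise_distances_argmin(z[const], km.cluster_centers_)
    # canonical relabeling: ascending peak-stage index of the centroid
    n_stages = x.shape[1]
    stage_idx = np.arange(n_stages, dtype=float)
    order_score = []
    for c in km.cluster_centers_:
        w = c - c.min()
        total = w.sum()
        order_score.append((w @ stage_idx) / total if total > 0 else n_stages / 2.0)
    rank = np.argsort(np.argsort(np.asarray(order_score), kind="stable"), kind="stable")
    groups = rank[labels] + 1
    return pd.Series(groups, index=means.index, name="group")
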