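"""Single-cell expression processing and technical QC.

Implements the RNA side of the joint pipeline: RPKM normalization, the
low-expression filter followed by quantile normalization, the per-cell
percentile-rank transform used for methylation-expression correlation,
library pass/fail QC, ERCC spike-in concordance, PCA, and the
merge-and-split technical-replicate check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

# working transform for PCA and concordance
LOG_PSEUDOCOUNT = 1.0
# a gene counts as detected in a cell when RPKM exceeds this
DETECTION_RPKM = 0.1


@dataclass
class ExpressionMatrix:
    """Genes x cells expression container with aligned layers.

    ``counts`` holds non-negative integers, ``rpkm`` non-negative reals and
    ``percentile`` per-cell percentile ranks in (0, 100].  ``cell_meta``
    carries per-cell metadata (``aligned_fraction``, ``fraction`` of
    cytosol/soma, library size).
    """

    counts: pd.DataFrame
    rpkm: pd.DataFrame | None = None
    percentile: pd.DataFrame | None = None
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for layer in (self.rpkm, self.percentile):
            if layer is not None and layer.shape != self.counts.shape:
                raise ValueError("expression layers must share dimensions")

    @property
    def cells(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)


def rpkm(counts: pd.DataFrame, exon_lengths: pd.Series,
         lib_sizes: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm[g, c] = counts[g, c] * 1e9 / (exon_lengths[g] * lib_sizes[c])``.
    """
    lengths = exon_lengths.reindex(counts.index)
    sizes = lib_sizes.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive exon length")
    if sizes.isna().any() or (sizes <= 0).any():
        raise ValueError("every cell needs a positive library size")
    return counts.mul(1e9).div(lengths, axis=0).div(sizes, axis=1)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Standard quantile normalization across columns.

    Each column's sorted values are replaced by the across-column mean of
    the per-rank values; tied values receive the mean of the rank values
    they span, so normalization is invariant to the order of ties.
    """
    arr = values.to_numpy(dtype=float)
    rank_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        base = np.empty_like(col)
        base[order] = rank_means
        # average rank values across exact ties
        s = pd.Series(base)
        out[:, j] = s.groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def filter_and_normalize(rpkm_layer: pd.DataFrame,
                         min_mean_rpkm: float = 0.1) -> pd.DataFrame:
    """Drop genes with cross-cell mean RPKM below threshold, then
    quantile-normalize the remaining matrix."""
    if rpkm_layer.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    keep = rpkm_layer.mean(axis=1) >= min_mean_rpkm
    filtered = rpkm_layer[keep]
    if filtered.empty:
        raise ValueError("all genes removed by the expression filter")
    return quantile_normalize(filtered)


def percentile_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Percentile rank: ``100 * rank / n`` with average ranks for ties.

    Output lies in (0, 100]; a constant vector maps to 100*(n+1)/(2n).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    return 100.0 * stats.rankdata(v, method="average") / v.size


def percentile_layer(rpkm_layer: pd.DataFrame) -> pd.DataFrame:
    """Apply the percentile transform per cell (column)."""
    return rpkm_layer.apply(lambda col: percentile_transform(col.to_numpy()), axis=0,
                            result_type="broadcast")


def library_qc(aligned_fraction: pd.Series, rpkm_layer: pd.DataFrame,
               min_aligned: float = 0.20, min_genes: int = 3000,
               rpkm_gate: float = 1.0) -> pd.DataFrame:
    """Per-library pass/fail report.

    A library fails on poor alignment (aligned fraction below
    ``min_aligned``) or poor gene coverage (fewer than ``min_genes`` genes
    with RPKM above ``rpkm_gate``).
    """
    n_detected = (rpkm_layer > rpkm_gate).sum(axis=0)
    rows = []
    for cell in rpkm_layer.columns:
        reasons = []
        af = float(aligned_fraction.get(cell, np.nan))
        if not af >= min_aligned:
            reasons.append("alignment")
        if int(n_detected[cell]) < min_genes:
            reasons.append("gene coverage")
        rows.append({
            "cell": cell,
            "aligned_fraction": af,
            "n_genes_rpkm_gt1": int(n_detected[cell]),
            "pass": not reasons,
            "failure_reasons": ";".join(reasons),
        })
    return pd.DataFrame(rows).set_index("cell")


def ercc_concordance(ercc_rpkm: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pairwise Pearson correlation of spike-in profiles between cells.

    Returns the symmetric correlation matrix (diagonal 1; pairs involving a
    zero-variance cell are NaN) and the minimum off-diagonal r, the QC
    summary quoted for technical concordance.
    """
    if ercc_rpkm.shape[1] < 2 or ercc_rpkm.shape[0] < 3:
        raise ValueError("need >=2 cells and >=3 spike-in genes")
    corr = ercc_rpkm.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    off = corr.values[~np.eye(len(corr), dtype=bool)]
    min_r = float(np.nanmin(off)) if np.isfinite(off).any() else float("nan")
    return corr, min_r


def pca_scores(matrix: pd.DataFrame, n_components: int = 2
               ) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of cells on mean-centered gene features.

    ``matrix`` is genes x cells; returns (cells x components score frame,
    explained-variance fractions, non-increasing and summing to <=1).
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    X = matrix.to_numpy(dtype=float).T
    n_components = min(n_components, min(X.shape))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores, index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_


def merge_split_concordance(pair_labels: pd.Series, rpkm_layer: pd.DataFrame
                            ) -> pd.DataFrame:
    """Within-pair vs between-pair similarity for merge-and-split replicates.

    ``pair_labels`` maps cell -> pair id (each id exactly twice).  Pearson
    correlation is computed on log2(RPKM + 1).  Returns one row per pair
    with the within-pair r, the mean between-pair r of its two members and
    the within > between indicator.
    """
    counts = pair_labels.value_counts()
    if (counts != 2).any():
        bad = counts[counts != 2].index.tolist()
        raise ValueError(f"pair labels not occurring exactly twice: {bad}")
    if len(counts) < 2:
        raise ValueError("need at least 2 pairs")
    logx = np.log2(rpkm_layer[pair_labels.index] + LOG_PSEUDOCOUNT)
    corr = logx.corr(method="pearson")
    rows = []
    for pair in counts.index:
        a, b = pair_labels.index[pair_labels == pair]
        within = float(corr.loc[a, b])
        others = pair_labels.index[pair_labels != pair]
        between = float(np.mean([corr.loc[a, o] for o in others]
                                + [corr.loc[b, o] for o in others]))
        rows.append({
            "pair": pair, "within_r": within, "between_r": between,
            "within_gt_between": within > between,
        })
    return pd.DataFrame(rows).set_index("pair")
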