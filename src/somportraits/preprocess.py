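"""Expression preprocessing: quantile normalization and log10 fold change.

The pipeline order is fixed: quantile-normalize the samples onto a common
distribution, transform to log10 scale, then center each gene on its cohort
mean. The centered values Δe (log-FC) are what the SOM and every downstream
stage consume; Δe = 0 means a gene sits exactly at its mean expression, and
positive/negative values mark over-/under-expression relative to the cohort.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ExpressionMatrix, LOGFC, RAW


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the mean empirical distribution.

    The reference distribution is the across-sample mean of the order
    statistics. Tied values within a column receive the mean of the reference
    quantiles spanned by their rank range, which keeps the transform symmetric
    under column permutations and makes the operation idempotent.
    """
    if matrix.scale != RAW:
        raise ValueError("quantile_normalize expects a raw-scale matrix")
    values = matrix.values
    n, m = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)

    out = np.empty_like(values)
    for j in range(m):
        col_sorted = sorted_vals[:, j]
        # collapse runs of tied values to the mean reference over their rank span
        boundaries = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        seg_sums = np.add.reduceat(reference, boundaries)
        seg_lens = np.diff(np.r_[boundaries, n])
        seg_means = seg_sums / seg_lens
        assigned = np.repeat(seg_means, seg_lens)
        out[order[:, j], j] = assigned

    df = matrix.data.copy()
    df.loc[:, :] = out
    return ExpressionMatrix(df, scale=RAW)


def log_fold_change(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log10-transform and center each gene on its mean over all samples."""
    if matrix.scale != RAW:
        raise ValueError("log_fold_change expects a raw-scale matrix")
    values = matrix.values
    if np.any(values <= 0):
        i, j = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"non-positive value at gene {matrix.gene_ids[i]!r}, sample "
            f"{matrix.sample_ids[j]!r}; log10 requires strictly positive input"
        )
    log_values = np.log10(values)
    centered = log_values - log_values.mean(axis=1, keepdims=True)
    df = matrix.data.copy()
    df.loc[:, :] = centered
    return ExpressionMatrix(df, scale=LOGFC)


def preprocess(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Full preprocessing chain: quantile normalization → log10 → centering."""
    return log_fold_change(quantile_normalize(matrix))
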