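"""Quantile normalization of probes x samples matrices.

Quantile normalization (QN) replaces each value with the mean of the values
holding the same rank on every array, forcing every column onto an identical
empirical distribution while preserving within-column rank order.  Ties within
a column receive the mean of the reference values at the tied ranks.
"""

from __future__ import annotations

import warnings

import numpy as np


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a features x samples matrix.

    Every output column is a monotone re-ranking of its input column onto the
    vector of row means of the column-sorted matrix, so all output columns
    share identical sorted values.

    Parameters
    ----------
    matrix : ndarray of shape (n_features, n_samples)
        Must be finite with at least two columns.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("quantile normalization needs a 2-D matrix with >= 2 columns")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values")
    n = X.shape[0]
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # tie groups are runs of equal values in the sorted column
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_col) != 0])
        sizes = np.diff(np.r_[starts, n])
        group_means = np.add.reduceat(reference, starts) / sizes
        out[order, j] = np.repeat(group_means, sizes)
    return out


def quantile_normalize_grouped(
    matrix: np.ndarray,
    row_groups: np.ndarray | None = None,
    join_columns: np.ndarray | None = None,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """QN applied independently within row groups, optionally joining a second matrix.

    ``row_groups`` labels each row (e.g. assay type I vs II); QN runs within
    each group separately.  When ``join_columns`` is given (the U matrix joined
    to the M matrix), the two matrices' columns are concatenated before QN so
    the channels are normalized against each other, and split back afterwards.
    Row and column order are unchanged.

    Returns the normalized matrix, or a ``(matrix, join_columns)`` pair when
    ``join_columns`` was supplied.
    """
    X = np.asarray(matrix, dtype=float)
    if row_groups is None:
        row_groups = np.zeros(X.shape[0], dtype=int)
    row_groups = np.asarray(row_groups)
    if row_groups.shape[0] != X.shape[0]:
        raise ValueError("row_groups length must match the number of rows")
    Y = None
    if join_columns is not None:
        Y = np.asarray(join_columns, dtype=float)
        if Y.shape != X.shape:
            raise ValueError("join_columns must have the same shape as matrix")
    out_x = np.empty_like(X)
    out_y = np.empty_like(Y) if Y is not None else None
    for g in np.unique(row_groups):
        idx = np.flatnonzero(row_groups == g)
        if idx.size == 1:
            warnings.warn(
                f"row group {g!r} has a single row; passing it through unnormalized",
                stacklevel=2,
            )
            out_x[idx] = X[idx]
            if Y is not None:
                out_y[idx] = Y[idx]
            continue
        if Y is None:
            out_x[idx] = quantile_normalize(X[idx])
        else:
            k = X.shape[1]
            combined = quantile_normalize(np.hstack([X[idx], Y[idx]]))
            out_x[idx] = combined[:, :k]
            out_y[idx] = combined[:, k:]
    if Y is not None:
        return out_x, out_y
    return out_x
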