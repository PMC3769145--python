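"""Independent reference implementations used only to check the package.

Deliberately naive (loops, pair enumeration, textbook formulas) and written
against the definitions, not against the package code.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def naive_quantile_normalize(matrix):
    """Sort/average/reassign quantile normalization, one value at a time.

    Ties within a column receive the mean of the reference values at the
    tied ranks.
    """
    X = np.asarray(matrix, dtype=float)
    n, k = X.shape
    reference = [
        sum(sorted(X[:, j])[i] for j in range(k)) / k for i in range(n)
    ]
    out = np.empty_like(X)
    for j in range(k):
        col = X[:, j]
        order = sorted(range(n), key=lambda i: col[i])
        i = 0
        while i < n:
            run = i
            while run + 1 < n and col[order[run + 1]] == col[order[i]]:
                run += 1
            tied_mean = sum(reference[i : run + 1]) / (run - i + 1)
            for t in range(i, run + 1):
                out[order[t], j] = tied_mean
            i = run + 1
    return out


def brute_force_auc(scores, positives):
    """AUC by enumerating every positive/negative pair (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    pos = scores[positives]
    neg = scores[~positives]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def welch_t_pvalue(a, b):
    """Two-sided Welch t-test from the textbook formulas."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df)
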