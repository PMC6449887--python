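"""Adjusted Rand Index for comparing a clustering against ground truth.

The ARI is the chance-corrected Rand index.  With contingency counts
``n_ij = |X_i ∩ Y_j|``, row sums ``a_i`` and column sums ``b_j`` over two
labelings of the same n cells,

    ARI = [ Σ_ij C(n_ij,2) − Σ_i C(a_i,2) Σ_j C(b_j,2) / C(n,2) ]
          / [ ½(Σ_i C(a_i,2) + Σ_j C(b_j,2)) − Σ_i C(a_i,2) Σ_j C(b_j,2) / C(n,2) ]

It equals 1 for identical partitions, is close to 0 for independent random
labelings, and can be negative when agreement is below chance.  All
choose-2 accumulation is done in exact integer arithmetic so the result is
exact even for tens of millions of cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ContingencySummary", "contingency", "adjusted_rand_index"]


@dataclass(frozen=True)
class ContingencySummary:
    """Pair-counting summary of the overlap between two labelings.

    ``n_ij[i, j]`` counts the cells carrying the i-th distinct label of X
    and the j-th distinct label of Y; ``a_i`` and ``b_j`` are the marginal
    class sizes and ``n`` the total number of cells.
    """

    n_ij: np.ndarray  # (r, s) int64
    a_i: np.ndarray  # (r,) int64 row sums
    b_j: np.ndarray  # (s,) int64 column sums
    n: int
    labels_x: np.ndarray
    labels_y: np.ndarray


def _as_labels(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr.astype(np.int64)


def contingency(labels_x, labels_y) -> ContingencySummary:
    """Exact contingency table between two integer labelings.

    Label values are arbitrary integers (the outlier code -1 included).
    """
    x = _as_labels(labels_x, "labels_x")
    y = _as_labels(labels_y, "labels_y")
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"label vectors differ in length: {x.shape[0]} vs {y.shape[0]}"
        )
    ux, xi = np.unique(x, return_inverse=True)
    uy, yi = np.unique(y, return_inverse=True)
    table = np.zeros((ux.size, uy.size), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    return ContingencySummary(
        n_ij=table,
        a_i=table.sum(axis=1),
        b_j=table.sum(axis=0),
        n=int(x.shape[0]),
        labels_x=ux,
        labels_y=uy,
    )


def _comb2_sum(counts: np.ndarray) -> int:
    c = counts.astype(object).ravel()
    return int((c * (c - 1) // 2).sum())


def _canonical(labels: np.ndarray) -> np.ndarray:
    # first-occurrence relabelling, for partition-identity checks
    _, inverse = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty(inverse.shape, dtype=np.int64)
    next_id = 0
    for pos, g in enumerate(inverse.ravel()):
        if g not in first:
            first[g] = next_id
            next_id += 1
        out[pos] = first[g]
    return out


def adjusted_rand_index(labels_x, labels_y, *, ignore_outliers: bool = False) -> float:
    """Adjusted Rand Index between two labelings of the same cells.

    Parameters
    ----------
    labels_x, labels_y
        Integer label vectors of equal length (n >= 2).  The outlier code
        -1 is treated as an ordinary cluster label by default.
    ignore_outliers
        If True, drop every position where either vector carries -1 before
        computing the index; how outlier-labelled cells should enter an
        accuracy comparison is a reporting choice, so both behaviours are
        exposed.

    Returns
    -------
    float in [-1, 1].  Negative values (agreement below chance) are
    returned as-is, never clamped.  When the chance-correction denominator
    is exactly zero (both partitions all-singletons, or both a single
    cluster) the index is defined as 1.0 for identical partitions and 0.0
    otherwise.
    """
    x = _as_labels(labels_x, "labels_x")
    y = _as_labels(labels_y, "labels_y")
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"label vectors differ in length: {x.shape[0]} vs {y.shape[0]}"
        )
    if ignore_outliers:
        keep = (x != -1) & (y != -1)
        x, y = x[keep], y[keep]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 cells to compute ARI")

    ct = contingency(x, y)
    sum_ij = _comb2_sum(ct.n_ij)
    sum_a = _comb2_sum(ct.a_i)
    sum_b = _comb2_sum(ct.b_j)
    pairs = ct.n * (ct.n - 1) // 2

    # ARI scaled by 2*C(n,2) to stay in exact integers until the division
    numerator = 2 * (pairs * sum_ij - sum_a * sum_b)
    denominator = pairs * (sum_a + sum_b) - 2 * sum_a * sum_b
    if denominator == 0:
        return 1.0 if np.array_equal(_canonical(x), _canonical(y)) else 0.0
    return numerator / denominator
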