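"""Bin connectivity, collective density and density-based bin classification.

Two bins are *directly connected* when the Euclidean distance between their
integer coordinate tuples is at most sqrt(eps).  Because coordinates are
integers, connectivity is decided on the squared-distance scale
(``dist**2 <= eps``), and a bin's neighbours are found by enumerating the
finite set of integer offset vectors with squared norm <= eps and probing a
hash table of occupied coordinates — never by an all-pairs scan.

Bins are then classified DBSCAN-style into CORE, BORDER and OUTLIER bins
from three density clauses, and connected core bins are grouped into
clusters by breadth-first search.
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from ._grid import BinAssignment, BinTable

__all__ = [
    "BinStatus",
    "BinGraph",
    "bin_distance",
    "enumerate_offsets",
    "find_neighbors",
    "collective_density",
    "identify_core_bins",
    "cluster_bins",
    "label_points",
]

OUTLIER_LABEL = -1


class BinStatus(IntEnum):
    """DBSCAN-style role of a bin."""

    OUTLIER = 0
    BORDER = 1
    CORE = 2


@dataclass(frozen=True)
class BinGraph:
    """Direct-connectivity structure over the non-empty bins.

    ``neighbors[i]`` is the sorted array of bin indices j != i with
    ``dist(C_i, C_j)**2 <= eps``; ``den_c`` is the collective density
    (own density plus all directly connected densities); ``status`` the
    CORE/BORDER/OUTLIER classification.
    """

    neighbors: list
    den_c: np.ndarray
    status: np.ndarray  # int8 vector of BinStatus values


def bin_distance(c_i, c_j) -> float:
    """Euclidean distance between two integer bin-coordinate tuples."""
    a = np.asarray(c_i, dtype=np.float64)
    b = np.asarray(c_j, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(
            f"coordinate tuples differ in length: {a.shape} vs {b.shape}"
        )
    return float(np.sqrt(((a - b) ** 2).sum()))


def enumerate_offsets(d: int, eps: float) -> np.ndarray:
    """All non-zero integer offset vectors in d dimensions with squared norm <= eps."""
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    r = math.isqrt(int(math.floor(eps)))
    axis = range(-r, r + 1)
    offs = [
        off
        for off in itertools.product(axis, repeat=d)
        if 0 < sum(o * o for o in off) <= eps
    ]
    if not offs:
        return np.empty((0, d), dtype=np.int64)
    return np.asarray(offs, dtype=np.int64)


def find_neighbors(bins: BinTable, eps: float) -> list:
    """Direct-connectivity adjacency over the non-empty bins.

    Equivalent to the O(N^2) definition (adjacent iff squared coordinate
    distance <= eps, self excluded) but computed with
    ``N * |offsets|`` constant-time hash probes.
    """
    coords = np.ascontiguousarray(bins.coords, dtype=np.int64)
    n = coords.shape[0]
    offsets = enumerate_offsets(coords.shape[1], eps)
    index = {c.tobytes(): i for i, c in enumerate(coords)}
    neighbors = [[] for _ in range(n)]
    for off in offsets:
        shifted = np.ascontiguousarray(coords + off)
        for i in range(n):
            j = index.get(shifted[i].tobytes())
            if j is not None:
                neighbors[i].append(j)
    return [np.asarray(sorted(ns), dtype=np.intp) for ns in neighbors]


def collective_density(bins: BinTable, neighbors: list) -> np.ndarray:
    """Collective density Den_c: sum of Den_b over all directly connected bins.

    A bin is at zero distance from itself and therefore directly connected
    to itself, so its own density is included in the sum: an isolated dense
    bin can still exceed the collective-density threshold.
    """
    den_b = bins.den_b
    den_c = den_b.astype(np.int64).copy()
    for i, ns in enumerate(neighbors):
        if len(ns):
            den_c[i] += int(den_b[ns].sum())
    return den_c


def identify_core_bins(
    bins: BinTable,
    neighbors: list,
    den_c: np.ndarray,
    min_den_b: float,
    min_den_c: float,
    rho: float,
) -> np.ndarray:
    """Classify every bin as CORE, BORDER or OUTLIER.

    Bin i is CORE iff all three hold:

    * ``den_b[i] > min_den_b``  (own density above the bin threshold),
    * ``den_c[i] > min_den_c``  (collective density above its threshold),
    * ``den_b[i]`` strictly exceeds the density of at least ``rho`` percent
      of its directly connected bins (self excluded from count and
      denominator; ties count against the bin; vacuously true with no
      neighbours).

    A non-core bin directly connected to a core bin is BORDER; anything
    else is OUTLIER.
    """
    den_b = bins.den_b
    n = bins.n_bins
    status = np.zeros(n, dtype=np.int8)
    for i in range(n):
        if den_b[i] <= min_den_b or den_c[i] <= min_den_c:
            continue
        ns = neighbors[i]
        if len(ns):
            exceeded = int((den_b[i] > den_b[ns]).sum())
            if exceeded * 100.0 < rho * len(ns):
                continue
        status[i] = BinStatus.CORE
    for i in range(n):
        if status[i] != BinStatus.CORE and any(
            status[j] == BinStatus.CORE for j in neighbors[i]
        ):
            status[i] = BinStatus.BORDER
    return status


def cluster_bins(status: np.ndarray, neighbors: list) -> tuple[np.ndarray, int]:
    """Group connected core bins into clusters by breadth-first search.

    Seeds are unvisited CORE bins in ascending bin-index order; the search
    expands only through CORE bins.  BORDER bins are absorbed into the
    first cluster whose search reaches them and are never expanded.
    OUTLIER bins keep the label -1.  Cluster ids are 0..K-1 in seed
    discovery order, making the labelling fully deterministic.
    """
    n = len(status)
    labels = np.full(n, OUTLIER_LABEL, dtype=np.int64)
    k = 0
    for seed in range(n):
        if status[seed] != BinStatus.CORE or labels[seed] != OUTLIER_LABEL:
            continue
        labels[seed] = k
        queue = deque([seed])
        while queue:
            i = queue.popleft()
            for j in neighbors[i]:
                if labels[j] != OUTLIER_LABEL:
                    continue
                if status[j] == BinStatus.CORE:
                    labels[j] = k
                    queue.append(j)
                elif status[j] == BinStatus.BORDER:
                    labels[j] = k
        k += 1
    return labels, k


def label_points(bin_labels: np.ndarray, assignment: BinAssignment) -> np.ndarray:
    """Propagate bin labels to cells: each cell inherits its bin's label."""
    return np.asarray(bin_labels, dtype=np.int64)[assignment.bin_of_cell]
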