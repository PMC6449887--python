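"""The FlowGrid clustering algorithm: grid-binned density-based clustering.

FlowGrid transfers DBSCAN's core/border/noise semantics from individual
points to the occupied bins of a uniform grid, so the clustering step
scales with the number of non-empty bins instead of the number of cells.
The pipeline is

    normalize -> assign_bins -> build_bin_table -> find_neighbors
    -> collective_density -> identify_core_bins -> cluster_bins
    -> label_points

and is fully deterministic for a fixed input and parameter set.  Cells in
outlier bins receive the label -1.

The scikit-learn-style estimator :class:`FlowGridClustering` is the main
entry point; :func:`flowgrid_cluster` is the equivalent function interface
exposing the per-bin results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import validate_data

from ._graph import (
    BinGraph,
    BinStatus,
    cluster_bins,
    collective_density,
    find_neighbors,
    identify_core_bins,
    label_points,
)
from ._grid import (
    BinTable,
    ExpressionMatrix,
    assign_bins,
    build_bin_table,
    normalize,
)

__all__ = ["GridConfig", "ClusterLabels", "flowgrid_cluster", "FlowGridClustering"]


@dataclass(frozen=True)
class GridConfig:
    """All user parameters of the algorithm.

    Parameters
    ----------
    n_bin
        Bins per dimension (>= 2).  Recommended range 4-15; data-set
        dependent.
    eps
        Connectivity radius on the squared-coordinate-distance scale: bins
        are directly connected when ``dist**2 <= eps``.  Recommended
        range 1-5.
    min_den_b
        A core bin's own density must strictly exceed this. Default 3.
    min_den_c
        A core bin's collective density must strictly exceed this.
        Default 40.
    rho
        Percentage (0, 100] of directly connected bins whose density a
        core bin must strictly exceed. Default 85.
    """

    n_bin: int
    eps: float
    min_den_b: float = 3.0
    min_den_c: float = 40.0
    rho: float = 85.0

    def __post_init__(self):
        if int(self.n_bin) != self.n_bin or self.n_bin < 2:
            raise ValueError(f"n_bin must be an integer >= 2, got {self.n_bin}")
        if not self.eps > 0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if not self.min_den_b > 0:
            raise ValueError(f"min_den_b must be positive, got {self.min_den_b}")
        if not self.min_den_c > 0:
            raise ValueError(f"min_den_c must be positive, got {self.min_den_c}")
        if not 0 < self.rho <= 100:
            raise ValueError(f"rho must be in (0, 100], got {self.rho}")


@dataclass(frozen=True)
class ClusterLabels:
    """Per-bin and per-cell cluster labels; -1 marks outliers."""

    bin_label: np.ndarray  # (N,) int64, -1 or 0..K-1
    cell_label: np.ndarray  # (n_cells,) int64
    n_clusters: int
    bin_table: BinTable = None
    bin_graph: BinGraph = None


def flowgrid_cluster(matrix, config: GridConfig) -> ClusterLabels:
    """Run the full clustering pipeline on an expression matrix.

    Parameters
    ----------
    matrix
        :class:`~flowgrid.ExpressionMatrix` or array of shape
        ``(n_cells, d)``; values must be finite (apply any arcsinh
        transform first).
    config
        Algorithm parameters.

    Returns
    -------
    ClusterLabels
        Per-bin and per-cell labels plus the intermediate bin table and
        connectivity graph.
    """
    normalized = normalize(matrix, config.n_bin)
    assignment = assign_bins(normalized, config.n_bin)
    table = build_bin_table(assignment)
    neighbors = find_neighbors(table, config.eps)
    den_c = collective_density(table, neighbors)
    status = identify_core_bins(
        table, neighbors, den_c, config.min_den_b, config.min_den_c, config.rho
    )
    bin_label, k = cluster_bins(status, neighbors)
    cell_label = label_points(bin_label, assignment)
    graph = BinGraph(neighbors=neighbors, den_c=den_c, status=status)
    return ClusterLabels(
        bin_label=bin_label,
        cell_label=cell_label,
        n_clusters=k,
        bin_table=table,
        bin_graph=graph,
    )


class FlowGridClustering(ClusterMixin, BaseEstimator):
    """Density-grid clustering for large single-cell cytometry matrices.

    A DBSCAN variant that bins cells onto a uniform grid and classifies
    the non-empty bins — rather than the cells — as core, border or
    outlier bins from their densities.  Connected core bins are merged by
    breadth-first search; every cell inherits its bin's cluster label, and
    cells in outlier bins are labelled ``-1``.  Runtime is dominated by
    the binning step and scales linearly with the number of cells.

    Parameters
    ----------
    n_bin : int, default=10
        Number of equal-width bins per dimension.  Together with ``eps``
        this is the parameter to tune per data set (try 4-15).
    eps : float, default=2.0
        Squared coordinate distance up to which bins count as directly
        connected (try 1-5).
    min_den_b : float, default=3
        Minimum own density (exclusive) for a core bin.
    min_den_c : float, default=40
        Minimum collective density (exclusive) for a core bin.
    rho : float, default=85
        Percentage of a core bin's directly connected bins that must be
        strictly less dense than it.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster label of each cell; ``-1`` for outliers.
    n_clusters_ : int
        Number of clusters found (excluding outliers).
    bin_coords_ : ndarray of shape (n_bins_, n_features_in_)
        Integer coordinates of the non-empty bins, lexicographically
        sorted.
    bin_counts_ : ndarray of shape (n_bins_,)
        Cells per non-empty bin (Den_b).
    bin_collective_counts_ : ndarray of shape (n_bins_,)
        Collective density per bin (Den_c).
    bin_status_ : ndarray of shape (n_bins_,)
        ``BinStatus`` code per bin (2 core, 1 border, 0 outlier).
    bin_labels_ : ndarray of shape (n_bins_,)
        Cluster label per bin; ``-1`` for outlier bins.
    n_bins_ : int
        Number of non-empty bins (N).

    Examples
    --------
    >>> import numpy as np
    >>> from flowgrid import FlowGridClustering
    >>> rng = np.random.default_rng(0)
    >>> X = np.vstack([rng.normal(0, 1, (500, 2)), rng.normal(8, 1, (500, 2))])
    >>> labels = FlowGridClustering(n_bin=10, eps=2).fit_predict(X)
    >>> len(set(labels) - {-1})
    2
    """

    def __init__(self, n_bin=10, eps=2.0, min_den_b=3.0, min_den_c=40.0, rho=85.0):
        self.n_bin = n_bin
        self.eps = eps
        self.min_den_b = min_den_b
        self.min_den_c = min_den_c
        self.rho = rho

    def fit(self, X, y=None):
        """Cluster the cells in X.

        Parameters
        ----------
        X : array-like of shape (n_samples, n_features)
            Expression matrix (cells x markers), finite values.
        y : Ignored

        Returns
        -------
        self : object
        """
        X = validate_data(self, X, ensure_min_samples=1, ensure_all_finite=True)
        config = GridConfig(
            n_bin=self.n_bin,
            eps=self.eps,
            min_den_b=self.min_den_b,
            min_den_c=self.min_den_c,
            rho=self.rho,
        )
        result = flowgrid_cluster(X, config)
        self.labels_ = result.cell_label
        self.n_clusters_ = result.n_clusters
        self.bin_coords_ = result.bin_table.coords
        self.bin_counts_ = result.bin_table.den_b
        self.bin_collective_counts_ = result.bin_graph.den_c
        self.bin_status_ = result.bin_graph.status
        self.bin_labels_ = result.bin_label
        self.n_bins_ = result.bin_table.n_bins
        self.outlier_fraction_ = float(np.mean(self.labels_ == -1))
        return self
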