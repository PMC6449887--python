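"""Uniform-grid binning of cytometry expression matrices.

Each marker dimension is rescaled onto ``[1, n_bin + 1]`` and every cell is
assigned the integer part of its rescaled value as a bin coordinate, giving
``n_bin`` equally sized bins per dimension.  Only non-empty bins are ever
materialised: with n cells in d dimensions the grid holds at most
``min(n, n_bin**d)`` occupied bins, which is what makes the downstream
density clustering scale with the number of bins rather than cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "BinAssignment",
    "BinTable",
    "normalize",
    "assign_bins",
    "build_bin_table",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """An ``n_cells x d`` matrix of marker intensities.

    Parameters
    ----------
    values
        Real matrix, one row per cell, one column per marker.  All entries
        must be finite; missing values are rejected rather than imputed.
    marker_names
        Column names, length ``d``.
    """

    values: np.ndarray
    marker_names: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got {values.ndim}-D")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError(f"matrix must be at least 1x1, got {values.shape}")
        names = tuple(str(n) for n in self.marker_names)
        if len(names) != values.shape[1]:
            raise ValueError(
                f"{len(names)} marker names for {values.shape[1]} columns"
            )
        _check_finite(values, names)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "marker_names", names)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BinAssignment:
    """Per-cell integer bin coordinates and bin membership.

    ``coords`` holds one d-tuple of coordinates in ``[1, n_bin]`` per cell;
    ``bin_of_cell`` maps every cell to the index of its (non-empty) bin,
    where bins are numbered ``0..N-1`` in ascending lexicographic order of
    their coordinate tuples.
    """

    coords: np.ndarray  # (n_cells, d) int64
    bin_of_cell: np.ndarray  # (n_cells,) intp
    n_bin: int


@dataclass(frozen=True)
class BinTable:
    """The sparse table of non-empty bins.

    One row per distinct coordinate tuple, in ascending lexicographic
    order.  ``den_b[i]`` is the bin density Den_b: the number of cells that
    fall in bin i.  ``members[i]`` lists the row indices of those cells.
    """

    coords: np.ndarray  # (N, d) int64, lexicographically sorted, distinct
    den_b: np.ndarray  # (N,) int64, positive
    members: list = field(repr=False, default=None)

    @property
    def n_bins(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def _check_finite(values: np.ndarray, names=None) -> None:
    bad = ~np.isfinite(values)
    if bad.any():
        col = int(np.nonzero(bad.any(axis=0))[0][0])
        label = names[col] if names is not None else f"column {col}"
        raise ValueError(
            f"non-finite values in marker {label!r}; "
            "remove or impute NaN/inf before clustering"
        )


def normalize(matrix, n_bin: int) -> np.ndarray:
    """Affinely rescale each dimension onto ``[1, n_bin + 1]``.

    The per-dimension minimum maps to 1 and the maximum to ``n_bin + 1``.
    A constant dimension has zero range, carries no clustering information,
    and is mapped entirely to 1 (with a warning).

    Parameters
    ----------
    matrix
        ``ExpressionMatrix`` or array-like of shape ``(n_cells, d)``.
    n_bin
        Number of bins per dimension, at least 2.
    """
    names = None
    if isinstance(matrix, ExpressionMatrix):
        names = matrix.marker_names
        values = matrix.values
    else:
        values = np.asarray(matrix, dtype=np.float64)
        if values.ndim == 1:
            values = values[:, None]
    if n_bin < 2:
        raise ValueError(f"n_bin must be >= 2, got {n_bin}")
    _check_finite(values, names)

    mins = values.min(axis=0)
    span = values.max(axis=0) - mins
    constant = span == 0
    if constant.any():
        cols = np.nonzero(constant)[0]
        labels = [names[c] if names else str(c) for c in cols]
        warnings.warn(
            f"constant dimension(s) {', '.join(labels)} mapped to a single bin",
            stacklevel=2,
        )
    safe_span = np.where(constant, 1.0, span)
    out = 1.0 + n_bin * (values - mins) / safe_span
    out[:, constant] = 1.0
    # guard against one-ulp overshoot of the affine endpoints
    np.clip(out, 1.0, n_bin + 1.0, out=out)
    return out


def assign_bins(normalized: np.ndarray, n_bin: int) -> BinAssignment:
    """Bin every cell by the integer part of its normalised coordinates.

    Values equal to ``n_bin + 1`` (the per-dimension maximum after
    normalisation) are clamped into the top bin ``n_bin``, so each
    dimension has exactly ``n_bin`` bins: half-open ``[k, k+1)`` except the
    last, which is closed.
    """
    normalized = np.asarray(normalized, dtype=np.float64)
    if normalized.ndim == 1:
        normalized = normalized[:, None]
    if normalized.size and (
        normalized.min() < 1.0 or normalized.max() > n_bin + 1.0
    ):
        raise ValueError(
            f"normalised values must lie in [1, {n_bin + 1}]; "
            f"got range [{normalized.min()}, {normalized.max()}]"
        )
    coords = np.floor(normalized).astype(np.int64)
    np.minimum(coords, n_bin, out=coords)
    # lexicographic bin ids; np.unique over rows sorts tuples lexicographically
    _, inverse = np.unique(coords, axis=0, return_inverse=True)
    return BinAssignment(
        coords=coords, bin_of_cell=inverse.ravel().astype(np.intp), n_bin=int(n_bin)
    )


def build_bin_table(assignment: BinAssignment) -> BinTable:
    """Materialise the table of non-empty bins from a cell assignment."""
    coords, counts = np.unique(assignment.coords, axis=0, return_counts=True)
    order = np.argsort(assignment.bin_of_cell, kind="stable")
    members = np.split(order, np.cumsum(counts)[:-1])
    return BinTable(coords=coords, den_b=counts.astype(np.int64), members=members)
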