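"""Synthetic cytometry-like data with known cluster structure.

Real cytometry expression matrices are multimodal: each cell population
forms a high-density, roughly Gaussian mode in marker space, populations
differ in abundance, and a small fraction of events (debris, doublets,
rare cells) falls in low-density regions between the modes.  The
generator emulates exactly that minimal structure — axis-aligned Gaussian
clusters of unequal size plus a uniform low-density outlier fraction over
a bounding box — so clustering accuracy, parameter robustness and runtime
scaling can be measured against a known ground truth without any
download.  Outlier events carry the truth label -1, matching the
clusterer's outlier code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._grid import ExpressionMatrix

__all__ = [
    "MixtureSpec",
    "well_separated_spec",
    "generate_mixture",
    "generate_scaling_series",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Full description of a Gaussian-mixture-plus-outliers data set.

    Parameters
    ----------
    n_cells
        Total number of events, clusters plus outliers.
    means
        ``(k, d)`` cluster means.
    scales
        ``(k, d)`` positive per-dimension standard deviations.
    weights
        Cluster weights on the simplex (sum to 1); cluster sizes are
        multinomial draws over the non-outlier events.
    outlier_fraction
        Fraction of events drawn uniformly over ``box``; in [0, 0.5].
    box
        ``(d, 2)`` per-dimension (low, high) bounds for outliers; default
        is the span of the means padded by half the smallest inter-mean
        distance.
    seed
        Fixes the full output.
    """

    n_cells: int
    means: np.ndarray
    scales: np.ndarray
    weights: np.ndarray
    outlier_fraction: float = 0.0
    box: np.ndarray = None
    seed: int = 0

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        scales = np.atleast_2d(np.asarray(self.scales, dtype=np.float64))
        if scales.shape == (1, 1):
            scales = np.full_like(means, scales[0, 0])
        weights = np.asarray(self.weights, dtype=np.float64)
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if scales.shape != means.shape:
            raise ValueError(
                f"scales shape {scales.shape} != means shape {means.shape}"
            )
        if (scales <= 0).any():
            raise ValueError("all scales must be positive")
        if weights.shape != (means.shape[0],):
            raise ValueError(
                f"{weights.size} weights for {means.shape[0]} clusters"
            )
        if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        if not 0.0 <= self.outlier_fraction <= 0.5:
            raise ValueError(
                f"outlier_fraction must be in [0, 0.5], got {self.outlier_fraction}"
            )
        box = self.box
        if box is None:
            box = _default_box(means, scales)
        box = np.asarray(box, dtype=np.float64)
        if box.shape != (means.shape[1], 2) or (box[:, 1] <= box[:, 0]).any():
            raise ValueError("box must be (d, 2) with low < high per dimension")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "box", box)

    @property
    def k(self) -> int:
        return self.means.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]


def _default_box(means: np.ndarray, scales: np.ndarray) -> np.ndarray:
    k = means.shape[0]
    if k > 1:
        diffs = means[:, None, :] - means[None, :, :]
        dists = np.sqrt((diffs**2).sum(-1))
        pad = 0.5 * dists[dists > 0].min()
    else:
        pad = 6.0 * scales.max()
    return np.stack([means.min(0) - pad, means.max(0) + pad], axis=1)


def well_separated_spec(
    n_cells: int = 10_000,
    d: int = 2,
    n_clusters: int = 4,
    outlier_fraction: float = 0.05,
    seed: int = 0,
    separation: float = 10.0,
    scale: float = 1.0,
    weights=None,
) -> MixtureSpec:
    """A well-separated benchmark mixture.

    Cluster means sit on a regular lattice with spacing ``separation``
    (default 10 = 10x the unit cluster scale, comfortably beyond the 6x
    separation at which Gaussian modes stop overlapping appreciably).
    With the default four clusters the weights are (0.4, 0.3, 0.2, 0.1),
    mimicking the unequal population abundances of real samples; other
    cluster counts default to equal weights.
    """
    side = int(np.ceil(n_clusters ** (1.0 / d)))
    grid = np.stack(
        np.meshgrid(*[np.arange(side)] * d, indexing="ij"), axis=-1
    ).reshape(-1, d)
    means = grid[:n_clusters].astype(np.float64) * separation
    scales = np.full((n_clusters, d), float(scale))
    if weights is None:
        if n_clusters == 4:
            weights = np.array([0.4, 0.3, 0.2, 0.1])
        else:
            weights = np.full(n_clusters, 1.0 / n_clusters)
    return MixtureSpec(
        n_cells=n_cells,
        means=means,
        scales=scales,
        weights=np.asarray(weights, dtype=np.float64),
        outlier_fraction=outlier_fraction,
        seed=seed,
    )


def generate_mixture(spec: MixtureSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw one data set from a mixture specification.

    Returns the expression matrix and the ground-truth labels: cluster
    indices ``0..k-1`` and -1 for the uniform outliers.  The rows are
    shuffled so cell order carries no information; everything is fixed by
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_out = int(round(spec.outlier_fraction * spec.n_cells))
    n_in = spec.n_cells - n_out
    counts = rng.multinomial(n_in, spec.weights)

    blocks, labels = [], []
    for c, (n_c, mean, scale) in enumerate(zip(counts, spec.means, spec.scales)):
        blocks.append(rng.normal(mean, scale, size=(n_c, spec.d)))
        labels.append(np.full(n_c, c, dtype=np.int64))
    if n_out:
        blocks.append(
            rng.uniform(spec.box[:, 0], spec.box[:, 1], size=(n_out, spec.d))
        )
        labels.append(np.full(n_out, -1, dtype=np.int64))

    values = np.vstack(blocks)
    truth = np.concatenate(labels)
    perm = rng.permutation(spec.n_cells)
    matrix = ExpressionMatrix(
        values=values[perm],
        marker_names=tuple(f"marker_{i+1}" for i in range(spec.d)),
    )
    return matrix, truth[perm]


def generate_scaling_series(spec: MixtureSpec, sizes) -> list:
    """The same mixture drawn at increasing n, for runtime-scaling studies.

    Each size gets a child seed derived from ``(spec.seed, size)`` so the
    series is reproducible and the draws are independent across sizes.
    """
    sizes = [int(s) for s in sizes]
    if sizes != sorted(sizes):
        raise ValueError("sizes must be ascending")
    out = []
    for n in sizes:
        child_seed = int(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(n,)).generate_state(1)[0]
            % (2**31)
        )
        child = MixtureSpec(
            n_cells=n,
            means=spec.means,
            scales=spec.scales,
            weights=spec.weights,
            outlier_fraction=spec.outlier_fraction,
            box=spec.box,
            seed=child_seed,
        )
        out.append(generate_mixture(child))
    return out
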