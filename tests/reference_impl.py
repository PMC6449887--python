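"""Independent brute-force reference implementations used as test oracles.

Everything here deliberately takes the slow, literal route — all-pairs
distances, explicit flood fill, pair enumeration — so it shares no code
path with the package's optimised hash-probe / BFS / contingency-table
implementations.
"""

from __future__ import annotations

import numpy as np


def brute_adjacency(coords: np.ndarray, eps: float) -> np.ndarray:
    """Boolean adjacency by checking every pair of bins."""
    c = np.asarray(coords, dtype=np.float64)
    d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
    adj = d2 <= eps
    np.fill_diagonal(adj, False)
    return adj


def brute_den_c(den_b: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """Collective density: own count plus every directly connected count."""
    den_b = np.asarray(den_b, dtype=np.int64)
    return den_b + adj @ den_b


def brute_status(
    den_b: np.ndarray,
    den_c: np.ndarray,
    adj: np.ndarray,
    min_den_b: float,
    min_den_c: float,
    rho: float,
) -> np.ndarray:
    """Apply the three core-bin clauses literally; 2 core, 1 border, 0 outlier."""
    n = len(den_b)
    status = np.zeros(n, dtype=np.int8)
    for i in range(n):
        neigh = np.nonzero(adj[i])[0]
        clause_b = den_b[i] > min_den_b
        clause_c = den_c[i] > min_den_c
        if len(neigh) == 0:
            clause_rho = True
        else:
            frac = np.sum(den_b[i] > den_b[neigh]) / len(neigh)
            clause_rho = frac >= rho / 100.0
        if clause_b and clause_c and clause_rho:
            status[i] = 2
    for i in range(n):
        if status[i] != 2 and any(status[j] == 2 for j in np.nonzero(adj[i])[0]):
            status[i] = 1
    return status


def brute_bin_labels(status: np.ndarray, adj: np.ndarray) -> tuple[np.ndarray, int]:
    """Cluster bins by explicit transitive closure over core-core edges.

    Components are numbered by their smallest core-bin index, and a border
    bin joins the adjacent core cluster with the smallest cluster id (the
    cluster discovered earliest) — the same deterministic rule the
    breadth-first implementation realises, derived independently.
    """
    n = len(status)
    labels = np.full(n, -1, dtype=np.int64)
    k = 0
    for start in range(n):
        if status[start] != 2 or labels[start] != -1:
            continue
        stack, comp = [start], {start}
        labels[start] = k
        while stack:
            i = stack.pop()
            for j in np.nonzero(adj[i])[0]:
                if status[j] == 2 and j not in comp:
                    comp.add(j)
                    labels[j] = k
                    stack.append(j)
        k += 1
    for i in range(n):
        if status[i] == 1:
            core_clusters = [labels[j] for j in np.nonzero(adj[i])[0] if status[j] == 2]
            labels[i] = min(core_clusters)
    return labels, k


def brute_ari(x, y) -> float:
    """ARI by enumerating all n(n-1)/2 pairs and correcting for chance."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    same_x = x[:, None] == x[None, :]
    same_y = y[:, None] == y[None, :]
    iu = np.triu_indices(n, k=1)
    sx, sy = same_x[iu], same_y[iu]
    n11 = int(np.sum(sx & sy))  # pairs together in both
    pairs_x = int(np.sum(sx))  # pairs together in x
    pairs_y = int(np.sum(sy))
    total = n * (n - 1) // 2
    expected = pairs_x * pairs_y / total
    maximum = 0.5 * (pairs_x + pairs_y)
    if maximum == expected:
        # both trivial partitions; identical iff pair relations agree everywhere
        return 1.0 if np.array_equal(sx, sy) else 0.0
    return (n11 - expected) / (maximum - expected)


def random_instance(rng: np.random.Generator):
    """A random small clustering problem: data plus algorithm parameters."""
    d = int(rng.integers(1, 5))
    n = int(rng.integers(50, 2001))
    k = int(rng.integers(1, 5))
    centers = rng.uniform(0.0, 10.0, size=(k, d))
    scales = rng.uniform(0.3, 2.0, size=(k, d))
    sizes = rng.multinomial(n - n // 10, np.full(k, 1.0 / k))
    parts = [
        rng.normal(centers[c], scales[c], size=(sizes[c], d)) for c in range(k)
    ]
    parts.append(rng.uniform(-2.0, 12.0, size=(n // 10, d)))
    values = np.vstack(parts)
    params = dict(
        n_bin=int(rng.integers(2, 11)),
        eps=float(rng.choice([1.0, 2.0, 3.0, 5.0])),
        min_den_b=float(rng.choice([0.5, 1.0, 3.0, 5.0])),
        min_den_c=float(rng.choice([5.0, 10.0, 40.0])),
        rho=float(rng.choice([50.0, 75.0, 85.0, 100.0])),
    )
    return values, params


def oracle_pipeline(values: np.ndarray, params: dict):
    """Run binning, then the brute-force definition clauses end to end.

    Binning (the affine rescale and integer part) is shared with the
    package; everything from connectivity onward is recomputed by the
    literal all-pairs route.  Returns (status, bin_labels, cell_labels).
    """
    from flowgrid import assign_bins, build_bin_table, normalize

    assignment = assign_bins(normalize(values, params["n_bin"]), params["n_bin"])
    table = build_bin_table(assignment)
    adj = brute_adjacency(table.coords, params["eps"])
    den_c = brute_den_c(table.den_b, adj)
    status = brute_status(
        table.den_b, den_c, adj,
        params["min_den_b"], params["min_den_c"], params["rho"],
    )
    bin_labels, _ = brute_bin_labels(status, adj)
    return status, bin_labels, bin_labels[assignment.bin_of_cell]
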