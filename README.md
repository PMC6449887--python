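# flowgrid

Ultrafast density-grid clustering for single-cell flow and mass cytometry
expression matrices, with the Adjusted Rand Index for evaluation against
manual gating and a synthetic-mixture generator with known ground truth.

## The problem

A cytometry experiment yields an `n_cells × d` matrix of marker
intensities for up to tens of millions of cells.  Cell populations appear
as high-density regions in marker space separated by low-density regions.
Manual gating — drawing population boundaries on 2-D scatter plots — is
subjective and impractical in high dimensions, and classic density-based
clustering (DBSCAN) over individual points does not scale to tens of
millions of events.

## The algorithm

FlowGrid moves DBSCAN's core/border/noise semantics from points to the
occupied bins of a uniform grid:

1. **Binning.** Each dimension is affinely rescaled to `[1, N_bin + 1]`
   and each cell's bin coordinate is the integer part of its rescaled
   value, giving a d-tuple `C_i` per non-empty bin.  Only the `N`
   non-empty bins are kept; `N ≤ min(n_cells, N_bin^d)`.
2. **Connectivity.** Bins `i, j` are *directly connected* iff
   `Dist(C_i, C_j) = sqrt(Σ_k (C_ik − C_jk)²) ≤ sqrt(ε)`, found by
   probing the finite set of integer offsets with squared norm ≤ ε
   against a hash table of occupied coordinates.
3. **Densities.** `Den_b(C_i)` is the number of cells in bin i;
   `Den_c(C_i) = Σ_{j directly connected to i} Den_b(C_j)` (a bin is at
   distance 0 from itself, so its own count is included).
4. **Classification.** Bin i is a **core** bin iff `Den_b > MinDen_b`,
   `Den_c > MinDen_c`, and `Den_b(C_i)` strictly exceeds the density of
   at least ρ% of its directly connected bins.  A non-core bin touching a
   core bin is a **border** bin; everything else is an **outlier** bin.
5. **Clusters.** Breadth-first search over core-core connections groups
   core bins into clusters; border bins join the first cluster to reach
   them.  Every cell inherits its bin's label; cells in outlier bins get
   `-1`.

Binning is `O(n_cells)` and dominates the runtime, so the algorithm
scales linearly in the number of cells for fixed `d`, `N_bin` and ε.

Accuracy against a reference labelling is measured by the Adjusted Rand
Index (chance-corrected pair agreement; 1 = identical partitions, ≈0 =
chance, negative below chance), computed in exact integer arithmetic.

## Worked example

```python
import numpy as np
from flowgrid import (FlowGridClustering, adjusted_rand_index,
                      generate_mixture, well_separated_spec)

spec = well_separated_spec(n_cells=10_000, d=2, n_clusters=4,
                           outlier_fraction=0.05, seed=0)
X, truth = generate_mixture(spec)

model = FlowGridClustering(n_bin=10, eps=2.0).fit(X.values)
print("non-empty bins N :", model.n_bins_)
print("clusters K       :", model.n_clusters_)
print("outlier fraction :", round(model.outlier_fraction_, 4))
print("ARI vs truth     :", round(adjusted_rand_index(truth, model.labels_), 4))
```

prints

```
non-empty bins N : 99
clusters K       : 4
outlier fraction : 0.0301
ARI vs truth     : 0.9606
```

10,000 cells occupy only 99 bins of the 10×10 grid; the four generated
populations are recovered as four clusters, 3% of cells fall in
low-density bins and are flagged `-1` (the generator planted 5% uniform
outliers, some of which land inside cluster bins), and the clustering
agrees with the generating partition at ARI 0.96.

The same pipeline is available from the shell:

```bash
flowgrid simulate --n 10000 --d 2 --k 4 --outlier-frac 0.05 --seed 0 \
    --output data.csv --truth truth.csv
flowgrid cluster --input data.csv --bin-n 10 --eps 2 --output labels.csv
flowgrid evaluate --truth truth.csv --pred labels.csv
```

`flowgrid cluster` also reads FCS 3.0/3.1 files (`--format fcs`,
`--columns` to select markers) and can apply the standard
`asinh(x/5)` cytometry transform first (`--arcsinh`, `--cofactor`).

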