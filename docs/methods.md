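# Methods

## Model and assumptions

FlowGrid assumes cell populations are high-density regions of marker
space separated by low-density regions, and that a uniform grid at the
right resolution resolves that structure: a population spans several
adjacent dense bins, while debris and rare events fall in sparse bins.
Density is computed per bin, not per cell, so the clustering stage works
on the `N` non-empty bins (`N ≤ min(n_cells, n_bin^d)`) and the overall
cost is dominated by the `O(n_cells)` binning pass.  The grid is uniform
and axis-aligned with the same `n_bin` in every dimension; adaptive or
per-dimension grids are out of scope.

## Parameters

| parameter   | meaning                                                        | default | notes |
|-------------|----------------------------------------------------------------|---------|-------|
| `n_bin`     | bins per dimension                                             | 10      | data-set dependent; 4–15 is the useful range. Too few bins merge populations, too many fragment them. |
| `eps`       | squared coordinate distance for direct connectivity            | 2.0     | data-set dependent; 1–5 is the useful range. `eps=1` connects axis neighbours only, `eps=2` adds diagonals. |
| `min_den_b` | core bin's own density must exceed this (strict)               | 3       | robust over 1–50 |
| `min_den_c` | core bin's collective density must exceed this (strict)        | 40      | robust over 10–300 |
| `rho`       | % of directly connected bins a core bin must strictly out-dense | 85      | robust over 70–95 |

`n_bin` and `eps` are the two parameters a user should tune per data
set; the estimator's defaults (10, 2.0) suit well-separated
low-dimensional data.  The three density thresholds are deliberately
insensitive: they prune the search for core bins rather than shape the
clusters, and the robustness suite measures exactly that.  An outlier
fraction above ~10% in the output is a sign the resolution parameters
are wrong for the data, and the CLI warns at that point.

All distances are compared on the squared scale (`dist² ≤ eps`), which
is exact for integer coordinates and avoids square roots in the hot
path.

## Numerical and procedural choices

* **Top edge.** The affine rescale sends each dimension's maximum to
  exactly `n_bin + 1`, whose integer part would be an out-of-range
  coordinate; it is clamped into the top bin, so bins are half-open
  `[k, k+1)` except the last, which is closed.  A one-ulp floating-point
  overshoot of the affine endpoints is clipped for the same reason.
* **Constant dimensions** have zero range, carry no clustering
  information, and map entirely to coordinate 1 with a warning.
  Non-finite values are rejected with an error naming the marker,
  never imputed.
* **Self-inclusion in `Den_c`.** A bin is at distance 0 from itself and
  is therefore directly connected to itself; its own count enters its
  collective density.  An isolated dense bin can thus still clear
  `min_den_c`.
* **The ρ clause** excludes the bin itself from both the count and the
  denominator (a bin can never strictly out-dense itself, and including
  it would cap the attainable fraction below 100%); ties count against
  the bin, and the clause is vacuously true for a bin with no
  neighbours.  Both density thresholds are strict inequalities.
* **Determinism.** Bins are indexed in ascending lexicographic
  coordinate order; BFS seeds and queues are processed in ascending bin
  index; cluster ids are 0-based in seed-discovery order.  A border bin
  adjacent to several core clusters joins the one discovered first —
  equivalently, the one containing the smallest core-bin index.  Output
  is therefore byte-identical across runs and invariant (up to nothing —
  exactly equal) under row permutation of the input.
* **Neighbour search** enumerates the integer offset vectors with
  squared norm ≤ eps once per run and probes a hash table of occupied
  coordinates: `N × |offsets|` O(1) lookups, identical in result to the
  all-pairs definition (property-tested against it).
* **ARI** is computed from the contingency table with exact integer
  choose-2 arithmetic (no overflow at tens of millions of cells) and is
  never clamped: below-chance agreement is reported negative.  When the
  chance-correction denominator is exactly zero (both partitions
  all-singletons or both a single cluster) the index is defined as 1.0
  for identical partitions and 0.0 otherwise.  Whether cells labelled
  `-1` should enter an accuracy comparison is a reporting choice, so
  `adjusted_rand_index(..., ignore_outliers=True)` optionally drops
  positions carrying `-1` in either vector.
* **Preprocessing.** The standard cytometry variance-stabilising
  transform `asinh(x / cofactor)` with cofactor 5 is provided and, when
  enabled, is applied before normalisation and binning.  It is opt-in
  per run, since whether it is appropriate depends on the instrument and
  panel.

## The synthetic generator

`generate_mixture` draws axis-aligned Gaussian clusters of unequal
abundance plus a uniform low-density outlier fraction over a bounding
box, with the outliers carrying truth label `-1`.  That is the minimal
structure matching the model's assumption of dense modes separated by
sparse regions.  The benchmark configuration (`well_separated_spec`)
places 4 cluster means on a lattice with spacing 10× the unit cluster
scale — comfortably beyond the ~6× separation at which Gaussian modes
stop overlapping — with weights (0.4, 0.3, 0.2, 0.1) mimicking unequal
population sizes, 5% outliers, and n = 10,000 cells in d = 2.

What the generator does **not** emulate: instrument noise models,
spillover/compensation structure, heavy-tailed or skewed marker
distributions, correlated (non-axis-aligned) covariances, rare
populations below the density floor, or real marker panels.  Passing the
recovery and robustness suites therefore shows the algorithm implements
its definitions correctly and behaves as designed on data matching its
assumptions — not that it will reach any particular accuracy on real
samples, where resolution tuning against reference gates is still
required.

## Problem sizes used in the checks

The definition-oracle suite compares the pipeline with a literal
all-pairs brute-force implementation on 100 random instances of up to
2,000 cells in up to 4 dimensions; the ARI implementation is compared
with a pair-enumeration oracle on 1,000 random label pairs of up to 50
elements; the runtime-scaling slope is fitted over 10⁴–10⁶ synthetic
cells, sizes chosen so the whole suite runs comfortably on a laptop.
The scaling measurement times only the clustering call, takes the best
of three runs at the smaller sizes to damp timer noise, and asserts the
log-log slope lies in [0.8, 1.3].

## Known limitations

* Grid resolution is global: a single `(n_bin, eps)` must suit all
  populations, so clusters at very different densities or scales can
  force a compromise (the classic limitation density-based methods
  inherit).
* In high dimensions the grid empties out (`N` approaches `n_cells`)
  and the bin-density signal vanishes; the method targets the low-
  dimensional panels typical of gating (2–10 markers).
* `n_bin` and `eps` are not selected automatically.
* The FCS support is a minimal list-mode reader/writer (FCS 3.0/3.1,
  float/double/integer data, little- or big-endian); analysis segments,
  multi-data-set files and delimiter escaping inside keyword values are
  not handled.
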