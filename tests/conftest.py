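import hypothesis
import numpy as np
import pytest

import flowgrid as fg

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def benchmark_mixture():
    """The well-separated 4-cluster benchmark: n=10,000, d=2, 5% outliers."""
    spec = fg.well_separated_spec(
        n_cells=10_000, d=2, n_clusters=4, outlier_fraction=0.05, seed=0
    )
    matrix, truth = fg.generate_mixture(spec)
    return spec, matrix, truth


@pytest.fixture(scope="session")
def benchmark_fit(benchmark_mixture):
    """Default-parameter fit (n_bin=10, eps=2) on the benchmark mixture."""
    _, matrix, _ = benchmark_mixture
    return fg.FlowGridClustering(n_bin=10, eps=2.0).fit(matrix.values)


def worked_example_layout():
    """2-D data whose occupied bins realise the worked-example layout.

    On a 10-bin grid: a three-bin chain (1,1)-(2,2)-(3,3) whose middle bin
    is the only core bin, an isolated bin (6,1), and a pair (9,9)-(10,10)
    whose denser member is core.  Bin densities are chosen so that with
    (eps=2, min_den_b=5, min_den_c=20, rho=75) the chain forms one
    cluster, the pair another, and the isolated bin's cells are outliers.
    """
    blocks = [
        ((1, 1), 8, (0.0, 0.0)),  # border; anchors the per-dimension minimum
        ((2, 2), 20, (1.3, 1.3)),  # core: denser than both neighbours
        ((3, 3), 7, (2.3, 2.3)),  # border
        ((6, 1), 6, (5.3, 0.3)),  # isolated -> outlier bin
        ((9, 9), 6, (8.3, 8.3)),  # border
        ((10, 10), 25, (10.0, 10.0)),  # core; anchors the maximum (clamped)
    ]
    rows, expected_coords, den = [], [], []
    for coord, count, point in blocks:
        rows.extend([point] * count)
        expected_coords.append(coord)
        den.append(count)
    values = np.asarray(rows, dtype=np.float64)
    return values, np.asarray(expected_coords), np.asarray(den)
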