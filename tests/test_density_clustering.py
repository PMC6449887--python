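"""Bin connectivity, density classification, BFS clustering, label propagation."""

import math

import numpy as np
import pytest

import flowgrid as fg
from flowgrid import BinStatus, BinTable
from conftest import worked_example_layout
from reference_impl import (
    brute_adjacency,
    brute_bin_labels,
    brute_den_c,
    brute_status,
    oracle_pipeline,
    random_instance,
)


def table_from_coords(coords, den_b=None):
    coords = np.asarray(coords, dtype=np.int64)
    if den_b is None:
        den_b = np.ones(len(coords), dtype=np.int64)
    return BinTable(coords=coords, den_b=np.asarray(den_b, dtype=np.int64))


def neighbors_to_sets(neighbors):
    return [set(map(int, ns)) for ns in neighbors]


class TestBinDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 1), (2, 2), math.sqrt(2)),
            ((3, 4, 5), (3, 4, 5), 0.0),
            ((1, 1, 1), (2, 3, 5), math.sqrt(21)),
        ],
    )
    def test_euclidean_over_integer_coordinates(self, a, b, expected):
        assert fg.bin_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fg.bin_distance((1, 2), (1, 2, 3))


class TestFindNeighbors:
    def test_worked_example_connectivity(self):
        # (1,1) and (2,2) lie sqrt(2) apart, within sqrt(eps) for eps=2;
        # (2,2) and (4,4) lie sqrt(8) apart, outside it
        t = table_from_coords([(1, 1), (2, 2), (4, 4)])
        ns = neighbors_to_sets(fg.find_neighbors(t, eps=2.0))
        assert ns == [{1}, {0}, set()]

    def test_eps_one_is_axis_aligned(self):
        t = table_from_coords([(2, 2), (1, 2), (3, 2), (2, 1), (2, 3), (3, 3)])
        ns = neighbors_to_sets(fg.find_neighbors(t, eps=1.0))
        # (2,2) touches its four unit-offset bins but not the diagonal (3,3)
        assert ns[0] == {1, 2, 3, 4}

    @pytest.mark.parametrize("eps", [1.0, 2.0, 3.0, 5.0])
    @pytest.mark.parametrize("d", [2, 3, 4])
    def test_matches_all_pairs_oracle(self, eps, d):
        rng = np.random.default_rng(d * 10 + int(eps))
        coords = np.unique(rng.integers(1, 8, size=(200, d)), axis=0)
        t = table_from_coords(coords)
        got = neighbors_to_sets(fg.find_neighbors(t, eps))
        adj = brute_adjacency(coords, eps)
        expected = [set(np.nonzero(row)[0].tolist()) for row in adj]
        assert got == expected

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        coords = np.unique(rng.integers(1, 10, size=(150, 3)), axis=0)
        ns = fg.find_neighbors(table_from_coords(coords), eps=3.0)
        for i, row in enumerate(ns):
            for j in row:
                assert i in ns[j]


class TestCollectiveDensity:
    def test_isolated_bin_keeps_own_density(self):
        t = table_from_coords([(1, 1), (5, 5)], den_b=[7, 3])
        ns = fg.find_neighbors(t, eps=2.0)
        np.testing.assert_array_equal(fg.collective_density(t, ns), [7, 3])

    def test_two_adjacent_bins_share_the_sum(self):
        t = table_from_coords([(1, 1), (2, 2)], den_b=[10, 15])
        ns = fg.find_neighbors(t, eps=2.0)
        np.testing.assert_array_equal(fg.collective_density(t, ns), [25, 25])

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(11)
        coords = np.unique(rng.integers(1, 7, size=(120, 3)), axis=0)
        den_b = rng.integers(1, 50, size=len(coords))
        t = table_from_coords(coords, den_b)
        ns = fg.find_neighbors(t, eps=3.0)
        expected = brute_den_c(den_b, brute_adjacency(coords, 3.0))
        np.testing.assert_array_equal(fg.collective_density(t, ns), expected)


class TestIdentifyCoreBins:
    def test_isolated_sparse_bin_is_outlier_under_defaults(self):
        t = table_from_coords([(1, 1)], den_b=[4])
        ns = fg.find_neighbors(t, eps=2.0)
        den_c = fg.collective_density(t, ns)
        status = fg.identify_core_bins(t, ns, den_c, 3.0, 40.0, 85.0)
        assert status[0] == BinStatus.OUTLIER  # den_c = 4 <= 40

    def test_isolated_dense_bin_is_core(self):
        # rho clause is vacuous without neighbours; den_c includes self
        t = table_from_coords([(1, 1)], den_b=[50])
        ns = fg.find_neighbors(t, eps=2.0)
        den_c = fg.collective_density(t, ns)
        status = fg.identify_core_bins(t, ns, den_c, 3.0, 40.0, 85.0)
        assert status[0] == BinStatus.CORE

    def test_strict_thresholds_and_ties(self):
        # den_b exactly at min_den_b fails ("larger than"); equal-density
        # neighbours count against the rho clause
        t = table_from_coords([(1, 1), (2, 2)], den_b=[30, 30])
        ns = fg.find_neighbors(t, eps=2.0)
        den_c = fg.collective_density(t, ns)
        status = fg.identify_core_bins(t, ns, den_c, 30.0, 10.0, 50.0)
        assert list(status) == [BinStatus.OUTLIER, BinStatus.OUTLIER]
        status = fg.identify_core_bins(t, ns, den_c, 3.0, 10.0, 50.0)
        # both pass den_b/den_c but each exceeds 0% of neighbours < 50%
        assert list(status) == [BinStatus.OUTLIER, BinStatus.OUTLIER]

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            coords = np.unique(
                rng.integers(1, 6, size=(rng.integers(5, 60), rng.integers(1, 4))),
                axis=0,
            )
            den_b = rng.integers(1, 60, size=len(coords))
            eps = float(rng.choice([1.0, 2.0, 5.0]))
            mdb, mdc, rho = (
                float(rng.choice([1, 3, 10])),
                float(rng.choice([5, 40, 100])),
                float(rng.choice([50, 85, 100])),
            )
            t = table_from_coords(coords, den_b)
            ns = fg.find_neighbors(t, eps)
            den_c = fg.collective_density(t, ns)
            got = fg.identify_core_bins(t, ns, den_c, mdb, mdc, rho)
            adj = brute_adjacency(coords, eps)
            expected = brute_status(den_b, brute_den_c(den_b, adj), adj, mdb, mdc, rho)
            np.testing.assert_array_equal(got, expected)


class TestClusterBins:
    def _status(self, codes):
        return np.asarray(codes, dtype=np.int8)

    def test_core_chain_forms_one_cluster(self):
        t = table_from_coords([(1, 1), (2, 2), (3, 3)])
        ns = fg.find_neighbors(t, eps=2.0)
        labels, k = fg.cluster_bins(self._status([2, 2, 2]), ns)
        assert k == 1
        assert list(labels) == [0, 0, 0]

    def test_disconnected_cores_form_two_clusters(self):
        t = table_from_coords([(1, 1), (2, 2), (8, 8), (9, 9)])
        ns = fg.find_neighbors(t, eps=2.0)
        labels, k = fg.cluster_bins(self._status([2, 2, 2, 2]), ns)
        assert k == 2
        assert list(labels) == [0, 0, 1, 1]

    def test_border_bin_inherits_adjacent_core_cluster(self):
        t = table_from_coords([(1, 1), (2, 2)])
        ns = fg.find_neighbors(t, eps=2.0)
        labels, k = fg.cluster_bins(self._status([1, 2]), ns)
        assert k == 1
        assert list(labels) == [0, 0]

    def test_border_never_bridges_two_core_clusters(self):
        # core - border - core in a chain: the border joins the earlier
        # cluster; expansion never passes through it
        t = table_from_coords([(1, 1), (2, 2), (3, 3)])
        ns = fg.find_neighbors(t, eps=2.0)
        labels, k = fg.cluster_bins(self._status([2, 1, 2]), ns)
        assert k == 2
        assert list(labels) == [0, 0, 1]

    def test_outlier_bins_keep_minus_one(self):
        t = table_from_coords([(1, 1), (5, 5)])
        ns = fg.find_neighbors(t, eps=2.0)
        labels, k = fg.cluster_bins(self._status([2, 0]), ns)
        assert list(labels) == [0, -1]


class TestLabelPoints:
    def test_cells_inherit_bin_labels(self):
        values = np.array([[0.0], [0.1], [9.9], [10.0]])
        assignment = fg.assign_bins(fg.normalize(values, 5), 5)
        cell = fg.label_points(np.array([3, -1]), assignment)
        assert list(cell) == [3, 3, -1, -1]

    def test_same_bin_same_label_property(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(300, 2))
        result = fg.flowgrid_cluster(values, fg.GridConfig(n_bin=6, eps=2.0))
        a = fg.assign_bins(fg.normalize(values, 6), 6)
        for b in range(result.bin_table.n_bins):
            cells = np.nonzero(a.bin_of_cell == b)[0]
            assert len(set(result.cell_label[cells])) == 1


class TestEndToEnd:
    def test_worked_example_layout(self):
        values, expected_coords, expected_den = worked_example_layout()
        config = fg.GridConfig(n_bin=10, eps=2.0, min_den_b=5, min_den_c=20, rho=75)
        result = fg.flowgrid_cluster(values, config)
        np.testing.assert_array_equal(result.bin_table.coords, expected_coords)
        np.testing.assert_array_equal(result.bin_table.den_b, expected_den)
        status = result.bin_graph.status
        assert list(status) == [
            BinStatus.BORDER,  # (1,1): chain end, absorbed by the core
            BinStatus.CORE,  # (2,2): denser than both neighbours
            BinStatus.BORDER,  # (3,3)
            BinStatus.OUTLIER,  # (6,1): isolated, fails collective density
            BinStatus.BORDER,  # (9,9)
            BinStatus.CORE,  # (10,10)
        ]
        assert result.n_clusters == 2
        assert list(result.bin_label) == [0, 0, 0, -1, 1, 1]
        # cells of the isolated bin carry the outlier label -1
        outlier_cells = result.cell_label == -1
        assert outlier_cells.sum() == 6

    def test_single_cell_is_outlier_under_defaults(self):
        with pytest.warns(UserWarning):  # single point: constant dimensions
            result = fg.flowgrid_cluster(
                np.array([[1.0, 2.0]]), fg.GridConfig(n_bin=10, eps=2.0)
            )
        assert result.n_clusters == 0
        assert list(result.cell_label) == [-1]

    def test_pipeline_matches_definition_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            values, params = random_instance(rng)
            result = fg.flowgrid_cluster(
                values,
                fg.GridConfig(
                    n_bin=params["n_bin"],
                    eps=params["eps"],
                    min_den_b=params["min_den_b"],
                    min_den_c=params["min_den_c"],
                    rho=params["rho"],
                ),
            )
            status, bin_labels, cell_labels = oracle_pipeline(values, params)
            np.testing.assert_array_equal(result.bin_graph.status, status)
            np.testing.assert_array_equal(result.bin_label, bin_labels)
            np.testing.assert_array_equal(result.cell_label, cell_labels)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(77)
        values, _ = random_instance(rng)
        config = fg.GridConfig(n_bin=8, eps=2.0)
        base = fg.flowgrid_cluster(values, config)
        perm = rng.permutation(len(values))
        permuted = fg.flowgrid_cluster(values[perm], config)
        np.testing.assert_array_equal(base.cell_label[perm], permuted.cell_label)

    def test_cluster_count_equals_core_subgraph_components(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            values, params = random_instance(rng)
            config = fg.GridConfig(**params)
            result = fg.flowgrid_cluster(values, config)
            status = result.bin_graph.status
            core = np.nonzero(status == BinStatus.CORE)[0]
            # independent component count via scipy on the core subgraph
            from scipy.sparse import lil_matrix
            from scipy.sparse.csgraph import connected_components

            m = lil_matrix((len(core), len(core)), dtype=np.int8)
            pos = {int(b): i for i, b in enumerate(core)}
            for b in core:
                for j in result.bin_graph.neighbors[b]:
                    if int(j) in pos:
                        m[pos[int(b)], pos[int(j)]] = 1
            k, _ = connected_components(m.tocsr(), directed=False)
            assert result.n_clusters == k

    def test_monotonicity_in_density_thresholds(self):
        rng = np.random.default_rng(13)
        values, params = random_instance(rng)

        def n_core(mdb, mdc):
            cfg = fg.GridConfig(
                n_bin=params["n_bin"], eps=params["eps"],
                min_den_b=mdb, min_den_c=mdc, rho=params["rho"],
            )
            res = fg.flowgrid_cluster(values, cfg)
            return int(np.sum(res.bin_graph.status == BinStatus.CORE))

        base = n_core(1.0, 5.0)
        counts_b = [n_core(m, 5.0) for m in (1, 2, 4, 8, 16, 32)]
        counts_c = [n_core(1.0, m) for m in (5, 10, 20, 40, 80, 160)]
        assert counts_b == sorted(counts_b, reverse=True)
        assert counts_c == sorted(counts_c, reverse=True)
        assert counts_b[0] == base


class TestDBSCANCorrespondence:
    def test_matches_dbscan_on_bin_centroids(self):
        """With the own-density and rho clauses disabled, a bin is core iff
        its collective density reaches min_samples — exactly DBSCAN run on
        every cell placed at its bin's centroid with radius sqrt(eps)."""
        from sklearn.cluster import DBSCAN

        rng = np.random.default_rng(3)
        for trial in range(10):
            d = int(rng.integers(1, 4))
            coords = rng.integers(1, 6, size=(rng.integers(40, 400), d))
            uniq, counts = np.unique(coords, axis=0, return_counts=True)
            t = table_from_coords(uniq, counts)
            eps = float(rng.choice([1.0, 2.0, 3.0]))
            min_samples = int(rng.integers(2, 20))
            ns = fg.find_neighbors(t, eps)
            den_c = fg.collective_density(t, ns)
            status = fg.identify_core_bins(
                t, ns, den_c,
                min_den_b=0.5,  # den_b >= 1 always passes
                min_den_c=min_samples - 1,  # den_c > m-1  <=>  den_c >= m
                rho=0.0,  # vacuous
            )
            expanded = np.repeat(uniq, counts, axis=0).astype(float)
            db = DBSCAN(eps=np.sqrt(eps), min_samples=min_samples).fit(expanded)
            is_core_point = np.zeros(len(expanded), bool)
            is_core_point[db.core_sample_indices_] = True
            first = np.concatenate([[0], np.cumsum(counts)[:-1]])
            for b in range(len(uniq)):
                rep = first[b]
                if status[b] == BinStatus.CORE:
                    assert is_core_point[rep]
                elif status[b] == BinStatus.BORDER:
                    assert not is_core_point[rep] and db.labels_[rep] != -1
                else:
                    assert db.labels_[rep] == -1
            # core-bin partition agrees with DBSCAN's partition of core points
            bin_labels, _ = fg.cluster_bins(status, ns)
            core_bins = np.nonzero(status == BinStatus.CORE)[0]
            if len(core_bins) > 1:
                mapping = {}
                for b in core_bins:
                    ours, theirs = int(bin_labels[b]), int(db.labels_[first[b]])
                    assert mapping.setdefault(ours, theirs) == theirs
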