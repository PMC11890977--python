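import numpy as np
import pytest

from sfcoupling.networks import SparsityGrid, sparsity_threshold
from sfcoupling.datatypes import ConnectivityMatrix, Modality
from sfcoupling.topology import (
    NullEnsembleParams,
    all_shortest_path_lengths,
    auc_curve,
    global_metrics,
    maslov_sneppen_rewire,
    metrics_over_sparsity,
    nodal_metrics,
)

from _oracles import (
    brute_betweenness,
    brute_char_path_length,
    brute_clustering,
    brute_global_efficiency,
    brute_local_efficiency,
    brute_nodal_efficiency,
    brute_nodal_path_length,
    floyd_warshall,
    random_er_adjacency,
)


def path_graph(n):
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1.0
    return a


def complete_graph(n):
    a = np.ones((n, n))
    np.fill_diagonal(a, 0.0)
    return a


class TestShortestPaths:
    def test_path_graph_distance(self):
        d = all_shortest_path_lengths(path_graph(3))
        assert d[0, 2] == 2.0

    def test_disconnected_dyads_are_infinite(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        d = all_shortest_path_lengths(a)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])
        assert d[0, 1] == 1.0

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            a = random_er_adjacency(rng, n, float(rng.uniform(0.2, 0.8)))
            np.testing.assert_array_equal(all_shortest_path_lengths(a), floyd_warshall(a))


class TestGlobalMetrics:
    def test_complete_graph_fixed_point(self):
        gm = global_metrics(complete_graph(4), nulls=NullEnsembleParams(n_nulls=5, seed=0))
        assert gm.Eglob == pytest.approx(1.0, abs=1e-15)
        assert gm.Eloc == pytest.approx(1.0, abs=1e-15)
        assert gm.Cp == pytest.approx(1.0, abs=1e-15)
        assert gm.Lp == pytest.approx(1.0, abs=1e-15)
        # no legal swap on a complete graph, so the nulls equal the input
        assert gm.Sigma == pytest.approx(1.0, abs=1e-15)
        assert not gm.disconnected

    def test_path_graph_enumeration_values(self):
        gm = global_metrics(path_graph(3))
        assert gm.Eglob == pytest.approx(5 / 6, abs=1e-12)  # 2*(1+1+0.5)/6
        assert round(gm.Eglob, 4) == 0.8333
        assert gm.Lp == pytest.approx(4 / 3, abs=1e-12)
        assert gm.Cp == 0.0

    def test_star_graph_has_zero_local_efficiency(self):
        a = np.zeros((4, 4))
        a[0, 1:] = 1.0
        a[1:, 0] = 1.0
        gm = global_metrics(a)
        assert gm.Eloc == 0.0

    def test_rejects_degenerate_order(self):
        with pytest.raises(ValueError, match="3 nodes"):
            global_metrics(np.zeros((2, 2)))

    def test_disconnected_graph_is_flagged_not_silently_averaged(self):
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 1.0
        a[2, 3] = a[3, 2] = 1.0
        gm = global_metrics(a)
        assert gm.disconnected
        assert np.isfinite(gm.Lp)  # mean over finite pairs only


class TestNodalMetrics:
    def test_path_graph_betweenness(self):
        nm = nodal_metrics(path_graph(3))
        np.testing.assert_allclose(nm.betweenness, [0.0, 1.0, 0.0], atol=1e-15)

    def test_complete_graph_degrees_and_betweenness(self):
        nm = nodal_metrics(complete_graph(4))
        np.testing.assert_array_equal(nm.degree, [3, 3, 3, 3])
        np.testing.assert_allclose(nm.betweenness, 0.0, atol=1e-15)

    def test_degree_equals_adjacency_row_sums(self):
        rng = np.random.default_rng(3)
        a = random_er_adjacency(rng, 10, 0.4)
        nm = nodal_metrics(a)
        np.testing.assert_array_equal(nm.degree, a.sum(axis=1))


def test_metric_battery_matches_brute_force_oracles():
    """Every global and nodal metric agrees with an independent brute-force
    implementation (Floyd-Warshall distances, neighbor-pair clustering,
    exhaustive shortest-path enumeration) on 200 random graphs."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = int(rng.integers(5, 13))
        a = random_er_adjacency(rng, n, float(rng.uniform(0.2, 0.8)))
        gm = global_metrics(a)
        nm = nodal_metrics(a)
        assert gm.Eglob == pytest.approx(brute_global_efficiency(a), abs=1e-12)
        assert np.mean(brute_local_efficiency(a)) == pytest.approx(gm.Eloc, abs=1e-12)
        assert gm.Cp == pytest.approx(np.mean(brute_clustering(a)), abs=1e-12)
        lp_oracle = brute_char_path_length(a)
        if np.isnan(lp_oracle):
            assert np.isnan(gm.Lp)
        else:
            assert gm.Lp == pytest.approx(lp_oracle, abs=1e-12)
        np.testing.assert_allclose(nm.NEglob, brute_nodal_efficiency(a), atol=1e-12)
        np.testing.assert_allclose(nm.NEloc, brute_local_efficiency(a), atol=1e-12)
        np.testing.assert_allclose(nm.NCp, brute_clustering(a), atol=1e-12)
        np.testing.assert_allclose(nm.betweenness, brute_betweenness(a), atol=1e-12)
        np.testing.assert_allclose(
            nm.NLp, brute_nodal_path_length(a), atol=1e-12, equal_nan=True
        )


class TestMaslovSneppen:
    def test_degree_sequence_preserved_in_every_null(self):
        rng = np.random.default_rng(11)
        a = random_er_adjacency(rng, 20, 0.3)
        nulls = maslov_sneppen_rewire(a, NullEnsembleParams(n_nulls=10, seed=4))
        for null in nulls:
            np.testing.assert_array_equal(null.sum(axis=1), a.sum(axis=1))
            assert null.sum() == a.sum()

    def test_complete_graph_has_no_legal_swap(self):
        with pytest.warns(UserWarning, match="no legal"):
            nulls = maslov_sneppen_rewire(complete_graph(5), NullEnsembleParams(n_nulls=3, seed=0))
        for null in nulls:
            np.testing.assert_array_equal(null, complete_graph(5))

    def test_rewiring_destroys_lattice_clustering(self):
        import networkx as nx

        g = nx.watts_strogatz_graph(50, 4, 0.0, seed=1)  # pure ring lattice
        a = nx.to_numpy_array(g)
        lattice_cp = np.mean(brute_clustering(a))
        nulls = maslov_sneppen_rewire(a, NullEnsembleParams(n_nulls=20, seed=2))
        null_cp = np.mean([np.mean(brute_clustering(x)) for x in nulls])
        assert null_cp < lattice_cp


class TestSweepAndAUC:
    def _z_matrix(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal((n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        labels = tuple(f"n{i}" for i in range(n))
        return ConnectivityMatrix(w, labels, Modality.FUNCTIONAL_WEIGHTED)

    def test_sweep_yields_one_metric_set_per_level(self):
        grid = SparsityGrid.default()
        sweep = metrics_over_sparsity(self._z_matrix(), grid)
        assert len(sweep) == 40

    def test_eglob_nondecreasing_in_sparsity(self):
        grid = SparsityGrid.from_range(0.05, 0.40, 0.05)
        sweep = metrics_over_sparsity(self._z_matrix(seed=5), grid)
        eglob = [lv.global_metrics.Eglob for lv in sweep]
        assert all(b >= a - 1e-12 for a, b in zip(eglob, eglob[1:]))

    def test_auc_of_constant_and_identity_curves(self):
        grid = SparsityGrid.default()
        assert auc_curve(np.full(40, 2.0), grid) == pytest.approx(0.39 * 2.0, abs=1e-12)
        assert auc_curve(grid.as_array, grid) == pytest.approx(0.079950, abs=1e-9)

    def test_auc_rejects_undefined_levels_and_degenerate_grids(self):
        grid = SparsityGrid.from_range(0.1, 0.3, 0.1)
        values = np.array([1.0, np.nan, 2.0])
        with pytest.raises(ValueError, match="0.2"):
            auc_curve(values, grid)
        single = SparsityGrid(values=(0.1,), step=0.1)
        with pytest.raises(ValueError, match="single-level"):
            auc_curve(np.array([1.0]), single)
        with pytest.raises(ValueError, match="grid of 3"):
            auc_curve(np.array([1.0]), grid)
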