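"""Graph metrics vs independent oracles, null model, AUC behavior."""

import networkx as nx
import numpy as np
import pytest

from wmtopo import (
    auc_over_sparsity,
    characteristic_path_length,
    degree_centrality,
    global_clustering,
    global_efficiency,
    local_efficiency,
    nodal_clustering,
    nodal_efficiency,
    nodal_local_efficiency,
    nodal_shortest_path_length,
    rewire_preserving_degree,
    shortest_path_lengths,
    smallworld_normalization,
    NullModelConfig,
)
from conftest import er_graph, ring_lattice
from oracles import (
    clustering_by_triple_enumeration,
    degrees_from_edge_list,
    floyd_warshall,
    global_efficiency_from_distances,
    local_efficiency_nodal,
)

TRIANGLE = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
PATH3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)


def star(n: int) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.int8)
    a[0, 1:] = a[1:, 0] = 1
    return a


class TestHandExamples:
    def test_complete_graph_degrees_and_lp(self):
        k4 = 1 - np.eye(4, dtype=np.int8)
        assert np.array_equal(degree_centrality(k4), [3, 3, 3, 3])
        assert characteristic_path_length(k4).value == 1.0
        assert global_efficiency(k4) == 1.0

    def test_star_degrees_and_clustering(self):
        s5 = star(5)
        assert np.array_equal(degree_centrality(s5), [4, 1, 1, 1, 1])
        assert nodal_clustering(s5)[0] == 0.0  # no neighbor-neighbor edges
        assert np.all(nodal_local_efficiency(s5) == 0.0)

    def test_triangle_clustering_and_local_efficiency(self):
        assert np.all(nodal_clustering(TRIANGLE) == 1.0)
        assert global_clustering(TRIANGLE) == 1.0
        assert local_efficiency(TRIANGLE) == 1.0

    def test_path_graph_distances_and_efficiency(self):
        d = shortest_path_lengths(PATH3)
        assert d[0, 2] == 2
        assert characteristic_path_length(PATH3).value == pytest.approx(4 / 3)
        assert global_efficiency(PATH3) == pytest.approx(5 / 6)

    def test_ring_of_five_path_length(self):
        ring = ring_lattice(5, 1)
        assert characteristic_path_length(ring).value == pytest.approx(1.5)

    def test_disconnected_pair_infinite_distance(self):
        a = np.zeros((4, 4), dtype=np.int8)
        a[0, 1] = a[1, 0] = 1
        d = shortest_path_lengths(a)
        assert np.isinf(d[0, 2])
        res = characteristic_path_length(a)
        assert res.disconnected
        assert np.isinf(nodal_shortest_path_length(a, 2))

    def test_totally_disconnected_efficiency_zero(self):
        assert global_efficiency(np.zeros((5, 5), dtype=np.int8)) == 0.0

    def test_empty_graph_lp_signaled(self):
        with pytest.raises(ValueError, match="no edges"):
            characteristic_path_length(np.zeros((4, 4), dtype=np.int8))


class TestOracleEquivalence:
    """Every metric against brute force / networkx on 50 random graphs."""

    def test_degree_matches_edge_list_tally(self, random_graphs):
        for adj in random_graphs:
            assert np.array_equal(degree_centrality(adj), degrees_from_edge_list(adj))

    def test_clustering_matches_triple_enumeration(self, random_graphs):
        for adj in random_graphs:
            np.testing.assert_allclose(
                nodal_clustering(adj), clustering_by_triple_enumeration(adj)
            )

    def test_clustering_matches_networkx(self, random_graphs):
        for adj in random_graphs[:20]:
            g = nx.from_numpy_array(adj)
            expected = np.array([nx.clustering(g, i) for i in range(adj.shape[0])])
            np.testing.assert_allclose(nodal_clustering(adj), expected)

    def test_distances_match_floyd_warshall(self, random_graphs):
        for adj in random_graphs:
            np.testing.assert_array_equal(
                shortest_path_lengths(adj), floyd_warshall(adj)
            )

    def test_efficiencies_match_oracles(self, random_graphs):
        for adj in random_graphs:
            d = floyd_warshall(adj)
            assert global_efficiency(adj) == pytest.approx(
                global_efficiency_from_distances(d)
            )
            np.testing.assert_allclose(
                nodal_local_efficiency(adj), local_efficiency_nodal(adj)
            )

    def test_global_efficiency_matches_networkx(self, random_graphs):
        for adj in random_graphs[:20]:
            g = nx.from_numpy_array(adj)
            assert global_efficiency(adj) == pytest.approx(nx.global_efficiency(g))

    def test_nodal_efficiency_from_distance_identity(self, random_graphs):
        # nodal efficiency equals the row mean of inverse distances
        for adj in random_graphs[:20]:
            d = floyd_warshall(adj)
            n = d.shape[0]
            with np.errstate(divide="ignore"):
                inv = np.where(np.isfinite(d), 1.0 / np.maximum(d, 1e-300), 0.0)
            np.fill_diagonal(inv, 0)
            np.testing.assert_allclose(nodal_efficiency(adj), inv.sum(1) / (n - 1))

    def test_permutation_invariance(self):
        adj = er_graph(18, 0.3, seed=9)
        rng = np.random.default_rng(4)
        perm = rng.permutation(18)
        padj = adj[np.ix_(perm, perm)]
        assert global_clustering(adj) == pytest.approx(global_clustering(padj))
        assert global_efficiency(adj) == pytest.approx(global_efficiency(padj))
        assert local_efficiency(adj) == pytest.approx(local_efficiency(padj))
        np.testing.assert_allclose(
            nodal_efficiency(adj)[perm], nodal_efficiency(padj)
        )


class TestRewiring:
    def test_degree_sequence_and_edge_count_preserved(self, random_graphs):
        for s, adj in enumerate(random_graphs):
            out = rewire_preserving_degree(adj, NullModelConfig(seed=s))
            assert np.array_equal(out.sum(0), adj.sum(0))
            assert np.array_equal(np.diag(out), np.zeros(adj.shape[0]))
            assert np.array_equal(out, out.T)

    def test_triangle_is_rigid(self):
        out = rewire_preserving_degree(TRIANGLE, NullModelConfig(seed=0))
        assert np.array_equal(out, TRIANGLE.astype(bool))

    def test_rewiring_destroys_lattice_triangles(self):
        lattice = ring_lattice(30, 3)
        c0 = global_clustering(lattice)
        lower = sum(
            global_clustering(
                rewire_preserving_degree(lattice, NullModelConfig(seed=s))
            )
            < c0
            for s in range(100)
        )
        assert lower >= 95

    def test_deterministic_given_seed(self):
        adj = er_graph(20, 0.3, seed=2)
        a = rewire_preserving_degree(adj, NullModelConfig(seed=7))
        b = rewire_preserving_degree(adj, NullModelConfig(seed=7))
        assert np.array_equal(a, b)


class TestSmallWorld:
    def test_rigid_graph_has_unit_indices(self):
        res = smallworld_normalization(TRIANGLE, NullModelConfig(n_random=5, seed=0))
        assert res.gamma == res.lam == res.sigma == 1.0

    def test_er_graph_is_its_own_null(self):
        # ER graphs are already random: gamma and lambda should sit near 1
        gs, ls = [], []
        for s in range(20):
            adj = er_graph(50, 0.25, seed=300 + s)
            res = smallworld_normalization(adj, NullModelConfig(n_random=8, seed=s))
            gs.append(res.gamma)
            ls.append(res.lam)
        assert np.mean(gs) == pytest.approx(1.0, abs=0.1)
        assert np.mean(ls) == pytest.approx(1.0, abs=0.05)

    def test_watts_strogatz_regime_sigma_above_one(self):
        # ring lattice with a few shortcuts: high clustering, short paths
        rng = np.random.default_rng(0)
        adj = ring_lattice(40, 3)
        for _ in range(8):
            i, j = rng.integers(0, 40, 2)
            if i != j:
                adj[i, j] = adj[j, i] = 1
        res = smallworld_normalization(adj, NullModelConfig(n_random=20, seed=1))
        assert res.sigma > 1.0


class TestAUC:
    GRID = tuple(round(0.05 * i, 2) for i in range(1, 11))

    def test_constant_one_integrates_to_grid_width(self):
        assert auc_over_sparsity(np.ones(10), self.GRID) == pytest.approx(0.45)

    def test_linear_values_integrate_exactly(self):
        grid = np.array(self.GRID)
        vals = 3.0 * grid + 1.0  # trapezoid rule is exact for linear functions
        expected = 1.5 * (0.5**2 - 0.05**2) + 1.0 * 0.45
        assert auc_over_sparsity(vals, grid) == pytest.approx(expected)

    def test_linearity_in_values(self):
        rng = np.random.default_rng(0)
        grid = np.array(self.GRID)
        u, v = rng.random(10), rng.random(10)
        assert auc_over_sparsity(2 * u + 3 * v, grid) == pytest.approx(
            2 * auc_over_sparsity(u, grid) + 3 * auc_over_sparsity(v, grid)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            auc_over_sparsity([1.0, 2.0], [0.1, 0.2, 0.3])
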