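"""Graph-metric checks against hand computations and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from scovnet import metrics
from .conftest import random_adjacency


def adjacency_from_edges(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        a[i, j] = a[j, i] = True
    return a


PATH3 = adjacency_from_edges(3, [(0, 1), (1, 2)])
TRIANGLE = adjacency_from_edges(3, [(0, 1), (1, 2), (0, 2)])
STAR5 = adjacency_from_edges(5, [(0, k) for k in range(1, 5)])


# ---------------------------------------------------------------------------
# independent oracles

def floyd_warshall(a):
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_clustering(a):
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if len(nbrs) < 2:
            continue
        links = sum(a[u, v] for u, v in itertools.combinations(nbrs, 2))
        out[i] = 2.0 * links / (len(nbrs) * (len(nbrs) - 1))
    return out


def brute_modularity(a, labels):
    """Pairwise-sum Newman-Girvan formula, independent of the per-community one."""
    m = a.sum() / 2.0
    deg = a.sum(axis=1)
    q = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += a[i, j] - deg[i] * deg[j] / (2.0 * m)
    return q / (2.0 * m)


def brute_local_efficiency(a):
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if len(nbrs) < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = floyd_warshall(sub)
        k = len(nbrs)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        out[i] = inv.sum() / (k * (k - 1))
    return out


# ---------------------------------------------------------------------------

class TestSmallExamples:
    def test_path_distances(self):
        d = metrics.shortest_path_lengths(PATH3)
        assert d[0, 2] == 2 and d[0, 1] == 1 and d[0, 0] == 0

    def test_disconnected_distance_infinite(self):
        a = adjacency_from_edges(4, [(0, 1), (2, 3)])
        d = metrics.shortest_path_lengths(a)
        assert np.isinf(d[0, 2])

    def test_global_efficiency_complete_graph(self):
        k5 = ~np.eye(5, dtype=bool)
        assert metrics.global_efficiency(k5) == pytest.approx(1.0)

    def test_global_efficiency_empty_graph(self):
        assert metrics.global_efficiency(np.zeros((4, 4), bool)) == 0.0

    def test_global_efficiency_path3(self):
        # pairs (0,1), (1,2) at distance 1; (0,2) at 2 -> (1+1+1/2)/3
        assert metrics.global_efficiency(PATH3) == pytest.approx(5.0 / 6.0)

    def test_local_efficiency_complete(self):
        k4 = ~np.eye(4, dtype=bool)
        mean, per_node = metrics.local_efficiency(k4)
        assert np.allclose(per_node, 1.0)

    def test_local_efficiency_star_is_zero(self):
        mean, per_node = metrics.local_efficiency(STAR5)
        assert mean == 0.0 and np.allclose(per_node, 0.0)

    def test_clustering_triangle(self):
        mean, per_node = metrics.clustering_coefficient(TRIANGLE)
        assert np.allclose(per_node, 1.0)

    def test_clustering_cycle5_zero(self):
        c5 = adjacency_from_edges(5, [(k, (k + 1) % 5) for k in range(5)])
        mean, _ = metrics.clustering_coefficient(c5)
        assert mean == 0.0

    def test_clustering_triangle_with_pendant(self):
        # neighbours of node 0: {1, 2, 3}; only (1, 2) connected -> 1/3
        a = adjacency_from_edges(4, [(0, 1), (1, 2), (0, 2), (0, 3)])
        _, per_node = metrics.clustering_coefficient(a)
        assert per_node[0] == pytest.approx(1.0 / 3.0)

    def test_path_length_complete(self):
        k6 = ~np.eye(6, dtype=bool)
        length, n_inf = metrics.characteristic_path_length(k6)
        assert length == pytest.approx(1.0) and n_inf == 0

    def test_path_length_path3(self):
        length, _ = metrics.characteristic_path_length(PATH3)
        assert length == pytest.approx(4.0 / 3.0)

    def test_path_length_flags_isolated_node(self):
        a = adjacency_from_edges(4, [(0, 1), (1, 2), (0, 2)])
        length, n_inf = metrics.characteristic_path_length(a)
        assert length == pytest.approx(1.0) and n_inf == 3

    def test_closeness_star_centre_and_leaf(self):
        c = metrics.closeness_centrality(STAR5)
        assert c[0] == pytest.approx(1.0)
        assert c[1] == pytest.approx(4.0 / 7.0)

    def test_closeness_disconnected_pair_of_edges(self):
        a = adjacency_from_edges(4, [(0, 1), (2, 3)])
        c = metrics.closeness_centrality(a)
        # within a 2-node component: mean distance 1, component scale 1/3
        assert np.allclose(c, 1.0 / 3.0)

    def test_modularity_two_triangles(self):
        a = adjacency_from_edges(
            6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        q = metrics.modularity_value(a, [1, 1, 1, 2, 2, 2])
        assert q == pytest.approx(0.5)

    def test_modularity_single_community_zero(self):
        a = adjacency_from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        assert metrics.modularity_value(a, np.ones(5)) == pytest.approx(0.0)

    def test_modularity_edgeless_graph_errors(self):
        with pytest.raises(ValueError, match="edgeless"):
            metrics.modularity_value(np.zeros((3, 3), bool), [1, 1, 2])


@pytest.fixture(scope="module")
def tiny_graphs():
    rng = np.random.default_rng(1234)
    return [random_adjacency(rng, int(rng.integers(2, 9)),
                             p_edge=rng.uniform(0.1, 0.9))
            for _ in range(200)]


class TestBruteForceOracles:
    """Every metric equals exhaustive recomputation on random tiny graphs."""

    def test_distances_match_floyd_warshall(self, tiny_graphs):
        for a in tiny_graphs:
            assert np.array_equal(metrics.shortest_path_lengths(a),
                                  floyd_warshall(a))

    def test_efficiencies_match_enumeration(self, tiny_graphs):
        for a in tiny_graphs:
            d = floyd_warshall(a)
            n = a.shape[0]
            with np.errstate(divide="ignore"):
                inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
            assert metrics.global_efficiency(a) == pytest.approx(
                inv.sum() / (n * (n - 1)), abs=1e-10)
            assert np.allclose(metrics.nodal_efficiency(a),
                               inv.sum(axis=1) / (n - 1), atol=1e-10)
            _, per_node = metrics.local_efficiency(a)
            assert np.allclose(per_node, brute_local_efficiency(a),
                               atol=1e-10)

    def test_clustering_matches_pair_counting(self, tiny_graphs):
        for a in tiny_graphs:
            _, per_node = metrics.clustering_coefficient(a)
            assert np.allclose(per_node, brute_clustering(a), atol=1e-10)

    def test_path_length_matches_enumeration(self, tiny_graphs):
        for a in tiny_graphs:
            d = floyd_warshall(a)[np.triu_indices(a.shape[0], 1)]
            finite = d[np.isfinite(d)]
            ours, n_inf = metrics.characteristic_path_length(a)
            assert n_inf == int(np.isinf(d).sum())
            if finite.size:
                assert ours == pytest.approx(finite.mean(), abs=1e-10)

    def test_closeness_matches_definition_and_networkx(self, tiny_graphs):
        for a in tiny_graphs:
            d = floyd_warshall(a)
            n = a.shape[0]
            expected = np.zeros(n)
            for i in range(n):
                finite = np.isfinite(d[i])
                r, total = finite.sum(), d[i][finite].sum()
                if r > 1 and total > 0:
                    expected[i] = (r - 1) ** 2 / ((n - 1) * total)
            ours = metrics.closeness_centrality(a)
            assert np.allclose(ours, expected, atol=1e-10)
        for a in tiny_graphs[:50]:
            g = nx.from_numpy_array(a.astype(int))
            ref = nx.closeness_centrality(g, wf_improved=True)
            assert np.allclose(metrics.closeness_centrality(a),
                               [ref[i] for i in range(a.shape[0])],
                               atol=1e-10)

    def test_modularity_matches_pairwise_formula(self, tiny_graphs):
        rng = np.random.default_rng(99)
        for a in tiny_graphs:
            if a.sum() == 0:
                continue
            labels = rng.integers(1, 4, size=a.shape[0])
            assert metrics.modularity_value(a, labels) == pytest.approx(
                brute_modularity(a, labels), abs=1e-10)


class TestSmallWorld:
    def test_er_graph_sigma_near_one(self):
        g = nx.gnm_random_graph(30, 90, seed=4)
        a = nx.to_numpy_array(g).astype(bool)
        sw = metrics.small_world_index(a, n_random=100, seed=0)
        assert 0.8 <= sw.sigma <= 1.2

    def test_watts_strogatz_ring_is_small_world(self):
        g = nx.watts_strogatz_graph(20, 4, p=0.1, seed=2)
        a = nx.to_numpy_array(g).astype(bool)
        sw = metrics.small_world_index(a, n_random=50, seed=0)
        assert sw.sigma > 1.5

    def test_isomorphic_relabeling_same_sigma(self):
        rng = np.random.default_rng(5)
        a = random_adjacency(rng, 12, 0.3)
        perm = rng.permutation(12)
        b = a[np.ix_(perm, perm)]
        sa = metrics.small_world_index(a, n_random=30, seed=11)
        sb = metrics.small_world_index(b, n_random=30, seed=11)
        # same observed C and L; null means agree within ensemble noise
        assert sa.clustering == pytest.approx(sb.clustering)
        assert sa.path_length == pytest.approx(sb.path_length)
        assert sa.sigma == pytest.approx(sb.sigma, rel=0.2)

    def test_rewiring_preserves_degrees(self):
        rng = np.random.default_rng(8)
        a = random_adjacency(rng, 15, 0.3)
        r = metrics.degree_preserving_rewire(a, np.random.default_rng(3))
        assert np.array_equal(a.sum(axis=1), r.sum(axis=1))


class TestMonotonicity:
    def test_adding_edge_never_hurts_efficiency_or_paths(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            a = random_adjacency(rng, 8, 0.3)
            free = np.transpose(np.nonzero(np.triu(~a, 1)))
            if len(free) == 0:
                continue
            i, j = free[rng.integers(len(free))]
            b = a.copy()
            b[i, j] = b[j, i] = True
            assert metrics.global_efficiency(b) >= \
                metrics.global_efficiency(a) - 1e-12
            da, db = (metrics.shortest_path_lengths(x) for x in (a, b))
            reachable = np.isfinite(da)
            assert (db[reachable] <= da[reachable]).all()

    def test_nodal_vectors_permutation_equivariant(self):
        rng = np.random.default_rng(23)
        a = random_adjacency(rng, 10, 0.4)
        perm = rng.permutation(10)
        b = a[np.ix_(perm, perm)]
        for fn in (metrics.nodal_efficiency, metrics.closeness_centrality,
                   lambda x: metrics.clustering_coefficient(x)[1],
                   lambda x: metrics.local_efficiency(x)[1]):
            assert np.allclose(fn(a)[perm], fn(b), atol=1e-12)
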