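"""Global and nodal metrics of binary undirected graphs.

All functions take a boolean (or 0/1) adjacency matrix with zero diagonal.
They are written directly against the standard definitions — breadth-first
shortest paths, triangle counting through matrix products, Newman-Girvan
modularity — rather than delegating to a graph library, so that the test
suite can hold them against independent implementations.

Conventions for disconnected graphs follow efficiency-based practice:
unreachable pairs contribute 1/inf = 0 to efficiencies, the characteristic
path length averages finite pairs only (and reports how many pairs were
infinite), and closeness centrality uses the Wasserman-Faust
within-component scaling (reachable-1)/(N-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path


def _as_adjacency(adj) -> np.ndarray:
    a = np.asarray(getattr(adj, "adjacency", adj))
    a = a.astype(bool)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not (a == a.T).all():
        raise ValueError("adjacency must be symmetric")
    if a.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    return a


def shortest_path_lengths(adj) -> np.ndarray:
    """All-pairs hop distances; unreachable pairs are ``inf``."""
    a = _as_adjacency(adj)
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    return _csgraph_shortest_path(a.astype(np.int8), method="D",
                                  unweighted=True, directed=False)


def _inverse_distances(dist: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & (dist > 0)
    inv[finite] = 1.0 / dist[finite]
    return inv


def global_efficiency(adj) -> float:
    """Mean inverse shortest path length over ordered pairs (1/inf = 0)."""
    a = _as_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        return 0.0
    inv = _inverse_distances(shortest_path_lengths(a))
    return float(inv.sum() / (n * (n - 1)))


def nodal_efficiency(adj) -> np.ndarray:
    """Per node, the mean inverse shortest path length to every other node."""
    a = _as_adjacency(adj)
    n = a.shape[0]
    inv = _inverse_distances(shortest_path_lengths(a))
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(adj) -> tuple[float, np.ndarray]:
    """Neighbourhood-subgraph efficiency per node, and its mean.

    For each node, the global efficiency of the subgraph induced on its
    neighbours; nodes of degree < 2 score 0.
    """
    a = _as_adjacency(adj)
    n = a.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(a[i])[0]
        if nbrs.size < 2:
            continue
        per_node[i] = global_efficiency(a[np.ix_(nbrs, nbrs)])
    return float(per_node.mean()) if n else 0.0, per_node


def clustering_coefficient(adj) -> tuple[float, np.ndarray]:
    """Watts-Strogatz clustering: mean C and per-node C_i.

    C_i = 2 * triangles(i) / (deg_i * (deg_i - 1)); 0 when deg_i < 2.
    """
    a = _as_adjacency(adj).astype(float)
    deg = a.sum(axis=1)
    # diag(A^3) counts each triangle at i twice (both orientations)
    triangles2 = ((a @ a) * a).sum(axis=1)
    denom = deg * (deg - 1)
    per_node = np.where(denom > 0, triangles2 / np.where(denom > 0, denom, 1),
                        0.0)
    return float(per_node.mean()) if a.shape[0] else 0.0, per_node


def characteristic_path_length(adj) -> tuple[float, int]:
    """Mean shortest path over finite pairs; also the infinite-pair count."""
    a = _as_adjacency(adj)
    n = a.shape[0]
    dist = shortest_path_lengths(a)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    n_infinite = int((~finite).sum())
    if finite.sum() == 0:
        return float("inf"), n_infinite
    return float(d[finite].mean()), n_infinite


def closeness_centrality(adj) -> np.ndarray:
    """Wasserman-Faust closeness: (r-1)^2 / ((N-1) * sum of distances).

    ``r`` is the number of nodes reachable from the node (including
    itself); isolated nodes score 0. On a connected graph this is the
    plain inverse of the average distance to all other nodes.
    """
    a = _as_adjacency(adj)
    n = a.shape[0]
    dist = shortest_path_lengths(a)
    out = np.zeros(n)
    for i in range(n):
        finite = np.isfinite(dist[i])
        r = int(finite.sum())  # includes i itself
        total = dist[i][finite].sum()
        if r > 1 and total > 0:
            out[i] = (r - 1) ** 2 / ((n - 1) * total)
    return out


def modularity_value(adj, partition) -> float:
    """Newman-Girvan Q = sum_c [ e_c/m - (d_c / 2m)^2 ].

    ``partition`` is a node -> community label array; ``m`` the number of
    edges, ``e_c`` the within-community edge count and ``d_c`` the sum of
    degrees in community ``c``.
    """
    a = _as_adjacency(adj).astype(float)
    labels = np.asarray(partition)
    if labels.shape[0] != a.shape[0]:
        raise ValueError("partition must assign every node a community")
    m = a.sum() / 2.0
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    deg = a.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        e_c = a[np.ix_(mask, mask)].sum() / 2.0
        d_c = deg[mask].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def degree_preserving_rewire(adj, rng: np.random.Generator,
                             n_swap_factor: int = 10) -> np.ndarray:
    """Randomize a graph by double edge swaps, preserving every degree.

    Attempts ``n_swap_factor * E`` swaps; a swap (a-b, c-d) -> (a-d, c-b)
    is applied only when it creates neither self-loops nor multi-edges.
    """
    a = _as_adjacency(adj).copy()
    edges = np.transpose(np.nonzero(np.triu(a, 1)))
    n_edges = len(edges)
    if n_edges < 2:
        return a
    edges = [tuple(e) for e in edges]
    attempts = n_swap_factor * n_edges
    for _ in range(attempts):
        k1, k2 = rng.integers(0, n_edges, size=2)
        if k1 == k2:
            continue
        u, v = edges[k1]
        x, y = edges[k2]
        if rng.random() < 0.5:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = False
        a[x, y] = a[y, x] = False
        a[u, x] = a[x, u] = True
        a[v, y] = a[y, v] = True
        edges[k1] = (u, x)
        edges[k2] = (v, y)
    return a


@dataclass(frozen=True)
class SmallWorldResult:
    sigma: float
    literal_ratio: float  # L / C, unnormalized
    clustering: float
    path_length: float
    clustering_random: float
    path_length_random: float
    n_random: int


def small_world_index(adj, n_random: int = 100,
                      seed: int | None = None) -> SmallWorldResult:
    """Normalized small-world index sigma = (C/C_rand) / (L/L_rand).

    The null ensemble is ``n_random`` degree-preserving rewirings of the
    graph; C_rand and L_rand are ensemble means. The unnormalized ratio
    L/C is reported alongside for transparency.
    """
    a = _as_adjacency(adj)
    if n_random < 1:
        raise ValueError("n_random must be at least 1")
    c_obs, _ = clustering_coefficient(a)
    l_obs, _ = characteristic_path_length(a)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for k in range(n_random):
        r = degree_preserving_rewire(a, rng)
        c_rand[k], _ = clustering_coefficient(r)
        l_rand[k], _ = characteristic_path_length(r)
    c_null = float(c_rand.mean())
    l_null = float(np.mean(l_rand[np.isfinite(l_rand)]))
    if c_null <= 0 or l_null <= 0 or not np.isfinite(l_obs):
        sigma = float("nan")
    else:
        sigma = (c_obs / c_null) / (l_obs / l_null)
    literal = l_obs / c_obs if c_obs > 0 else float("inf")
    return SmallWorldResult(sigma=float(sigma), literal_ratio=float(literal),
                            clustering=c_obs, path_length=l_obs,
                            clustering_random=c_null,
                            path_length_random=l_null, n_random=n_random)


@dataclass(frozen=True)
class GlobalMetrics:
    """All global measures of one density graph."""

    density: float
    characteristic_path_length: float
    n_infinite_pairs: int
    global_efficiency: float
    local_efficiency: float
    mean_clustering: float
    modularity: float
    small_world_sigma: float
    small_world_literal_ratio: float


def global_metrics(graph, partition=None, n_random: int = 100,
                   seed: int | None = None,
                   louvain_seed: int = 0,
                   louvain_restarts: int = 20) -> GlobalMetrics:
    """Convenience bundle of every global measure for one graph.

    When no partition is supplied, Louvain (best of ``louvain_restarts``)
    provides the partition scored by modularity.
    """
    a = _as_adjacency(graph)
    density = getattr(graph, "density", float("nan"))
    if partition is None:
        from .community import louvain_partition
        partition = louvain_partition(a, seed=louvain_seed,
                                      n_restarts=louvain_restarts).labels
    length, n_inf = characteristic_path_length(a)
    c_mean, _ = clustering_coefficient(a)
    le_mean, _ = local_efficiency(a)
    sw = small_world_index(a, n_random=n_random, seed=seed)
    return GlobalMetrics(
        density=float(density),
        characteristic_path_length=length,
        n_infinite_pairs=n_inf,
        global_efficiency=global_efficiency(a),
        local_efficiency=le_mean,
        mean_clustering=c_mean,
        modularity=modularity_value(a, partition),
        small_world_sigma=sw.sigma,
        small_world_literal_ratio=sw.literal_ratio,
    )


def nodal_metrics(graph, regions=None):
    """Per-node efficiency, clustering and closeness as a DataFrame."""
    import pandas as pd

    a = _as_adjacency(graph)
    regions = regions if regions is not None \
        else getattr(graph, "regions", range(a.shape[0]))
    _, clustering = clustering_coefficient(a)
    _, local_eff = local_efficiency(a)
    return pd.DataFrame({
        "region": list(regions),
        "nodal_efficiency": nodal_efficiency(a),
        "nodal_local_efficiency": local_eff,
        "nodal_clustering": clustering,
        "closeness_centrality": closeness_centrality(a),
    })
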