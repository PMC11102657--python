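"""Independent brute-force oracles for the graph-metric tests.

Deliberately naive implementations (triple enumeration, Floyd–Warshall,
union–find, edge-list tallies) kept separate from the package so metric
tests compare two independent code paths.
"""

from __future__ import annotations

import numpy as np


def degrees_from_edge_list(adj: np.ndarray) -> np.ndarray:
    """Tally node incidences from the explicit edge list."""
    n = adj.shape[0]
    deg = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                deg[i] += 1
                deg[j] += 1
    return deg


def clustering_by_triple_enumeration(adj: np.ndarray) -> np.ndarray:
    """C_i by O(n^3) enumeration of neighbor pairs."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k) if adj[nb[a], nb[b]]
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop distances by dynamic programming."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency_nodal(adj: np.ndarray) -> np.ndarray:
    """Composition of oracles: induced neighbor subgraph + Eg oracle."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        out[i] = global_efficiency_from_distances(floyd_warshall(sub))
    return out


def connected_by_union_find(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)}) == 1
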