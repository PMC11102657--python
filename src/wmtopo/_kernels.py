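"""Numerical kernels for the metric hot loops.

Compiled with numba when available; the pure-Python fallbacks are
bit-identical (same RNG stream, same arithmetic), just slower.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def local_efficiency_kernel(adj: np.ndarray) -> np.ndarray:
    """Per-node local efficiency of a binary graph.

    ``adj`` is a symmetric uint8 adjacency with zero diagonal.  For every
    node, runs one BFS per neighbor inside the neighbor-induced subgraph
    and accumulates inverse distances.
    """
    n = adj.shape[0]
    out = np.zeros(n)
    nb = np.empty(n, np.int64)
    dist = np.empty(n, np.int64)
    queue = np.empty(n, np.int64)
    for i in range(n):
        k = 0
        for j in range(n):
            if adj[i, j]:
                nb[k] = j
                k += 1
        if k < 2:
            continue
        total = 0.0
        for s in range(k):
            for a in range(k):
                dist[a] = -1
            dist[s] = 0
            queue[0] = s
            qh, qt = 0, 1
            while qh < qt:
                u = queue[qh]
                qh += 1
                du = dist[u]
                un = nb[u]
                for a in range(k):
                    if dist[a] < 0 and adj[un, nb[a]]:
                        dist[a] = du + 1
                        queue[qt] = a
                        qt += 1
            for a in range(k):
                if a != s and dist[a] > 0:
                    total += 1.0 / dist[a]
        out[i] = total / (k * (k - 1))
    return out


@njit(cache=True)
def double_edge_swap_kernel(
    adj: np.ndarray,
    edges: np.ndarray,
    ai: np.ndarray,
    bi: np.ndarray,
    flip: np.ndarray,
) -> None:
    """Apply a pre-drawn sequence of double-edge-swap attempts in place.

    ``adj`` (uint8, symmetric) and ``edges`` ((m, 2) int64, i < j) are
    mutated.  Attempt t proposes swapping edges ``ai[t]`` and ``bi[t]``
    (endpoint order flipped when ``flip[t]``); attempts creating self-loops
    or multi-edges are skipped.
    """
    for t in range(len(ai)):
        p, q = ai[t], bi[t]
        if p == q:
            continue
        u, v = edges[p, 0], edges[p, 1]
        x, y = edges[q, 0], edges[q, 1]
        if flip[t]:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        if adj[u, y] or adj[v, x]:
            continue
        adj[u, v] = 0
        adj[v, u] = 0
        adj[x, y] = 0
        adj[y, x] = 0
        adj[u, y] = 1
        adj[y, u] = 1
        adj[v, x] = 1
        adj[x, v] = 1
        if u < y:
            edges[p, 0], edges[p, 1] = u, y
        else:
            edges[p, 0], edges[p, 1] = y, u
        if v < x:
            edges[q, 0], edges[q, 1] = v, x
        else:
            edges[q, 0], edges[q, 1] = x, v
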