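"""Global and nodal graph metrics on binary undirected networks.

Implements the standard unweighted graph-theory measures used in structural
connectomics — clustering coefficient, characteristic path length, global /
local / nodal efficiency, degree centrality — together with the
degree-preserving rewiring null model used to normalize clustering and path
length into the small-world indices gamma, lambda and sigma = gamma/lambda,
and the trapezoidal area-under-curve summary over a sparsity sweep.

Conventions (matching the usual binary-network toolbox definitions):

* clustering of a node with degree < 2 is 0 and such nodes contribute 0 to
  the network mean;
* efficiency-type metrics treat unreachable pairs as contributing 0
  (``1/inf = 0``), so they are well defined on disconnected graphs;
* the characteristic path length averages hop distances over *reachable*
  ordered pairs only and carries a flag when any pair is unreachable.

All functions accept either a :class:`~wmtopo.construct.BinaryNetwork` or a
plain symmetric 0/1 adjacency array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._kernels import double_edge_swap_kernel, local_efficiency_kernel
from .construct import BinaryNetwork

__all__ = [
    "NullModelConfig",
    "CharPathResult",
    "SmallWorldResult",
    "GlobalMetricsProfile",
    "NodalMetricsTable",
    "degree_centrality",
    "nodal_clustering",
    "global_clustering",
    "shortest_path_lengths",
    "nodal_shortest_path_length",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_efficiency",
    "nodal_local_efficiency",
    "local_efficiency",
    "rewire_preserving_degree",
    "smallworld_normalization",
    "auc_over_sparsity",
    "global_profile",
    "nodal_profile",
    "subject_profiles",
]

GLOBAL_METRICS = ("Cp", "Lp", "Eg", "Eloc", "Gamma", "Lambda", "Sigma")
NODAL_METRICS = (
    "clustering",
    "path_length",
    "efficiency",
    "local_efficiency",
    "degree",
)


def _adj(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    return a.astype(bool)


@dataclass(frozen=True)
class NullModelConfig:
    """Degree-preserving rewiring null model settings.

    ``n_random`` surrogates are generated per network; each surrogate is the
    result of ``swaps_per_edge * edge_count`` attempted double-edge swaps.
    """

    n_random: int = 100
    swaps_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_random < 1:
            raise ValueError("n_random must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")


class CharPathResult(NamedTuple):
    """Characteristic path length with a reachability flag."""

    value: float
    disconnected: bool


class SmallWorldResult(NamedTuple):
    """Normalized clustering, path length and their ratio."""

    gamma: float
    lam: float
    sigma: float
    connected: bool


# ---------------------------------------------------------------------------
# basic metrics


def degree_centrality(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Node degrees ``k_i`` (row sums of the adjacency matrix)."""
    return _adj(net).sum(axis=1).astype(np.int64)


def nodal_clustering(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Per-node clustering ``C_i = 2 t_i / (k_i (k_i - 1))``.

    ``t_i`` is the number of triangles through node ``i``; nodes with fewer
    than two neighbors get ``C_i = 0``.
    """
    a = _adj(net).astype(np.float64)
    k = a.sum(axis=1)
    t = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return c


def global_clustering(net: BinaryNetwork | np.ndarray) -> float:
    """Network clustering coefficient: the mean of nodal clustering."""
    return float(nodal_clustering(net).mean())


def shortest_path_lengths(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs hop-count distance matrix; unreachable pairs are ``inf``."""
    a = _adj(net)
    return shortest_path(csr_matrix(a), method="D", unweighted=True)


def nodal_shortest_path_length(
    net: BinaryNetwork | np.ndarray, node: int | None = None
) -> np.ndarray | float:
    """Mean hop distance from each node to the nodes it can reach.

    Returns the full per-node vector, or a scalar when ``node`` is given.
    Isolated nodes (nothing reachable) get ``inf``.
    """
    d = shortest_path_lengths(net)
    np.fill_diagonal(d, np.inf)  # exclude self-distance from the mean
    finite = np.isfinite(d)
    counts = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / counts, np.inf)
    return out if node is None else float(out[node])


def characteristic_path_length(net: BinaryNetwork | np.ndarray) -> CharPathResult:
    """Mean hop distance over all reachable ordered pairs.

    Raises ``ValueError`` on an empty (edgeless) graph; flags graphs where
    any pair is unreachable.
    """
    d = shortest_path_lengths(net)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_reach = int(finite.sum())
    if n_reach == 0:
        raise ValueError("characteristic path length undefined: graph has no edges")
    lp = float(d[finite].sum() / n_reach)
    return CharPathResult(lp, disconnected=n_reach < n * (n - 1))


def _efficiency_from_dist(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """``E_g = mean over ordered pairs of 1/d_ij`` with ``1/inf = 0``."""
    with np.errstate(divide="ignore"):
        return _efficiency_from_dist(shortest_path_lengths(net))


def nodal_efficiency(
    net: BinaryNetwork | np.ndarray, node: int | None = None
) -> np.ndarray | float:
    """Efficiency of transfer from each node: ``mean_j 1/d_ij`` over j != i."""
    d = shortest_path_lengths(net)
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    out = inv.sum(axis=1) / (n - 1)
    return out if node is None else float(out[node])


def _subgraph_distances(sub: np.ndarray) -> np.ndarray:
    """All-pairs hop distances in a small dense boolean adjacency.

    Level-synchronous BFS via repeated boolean matrix products — much faster
    than a sparse-graph call for the tiny neighbor subgraphs this serves.
    """
    k = sub.shape[0]
    d = np.full((k, k), np.inf)
    np.fill_diagonal(d, 0.0)
    d[sub] = 1.0
    reach = sub | np.eye(k, dtype=bool)
    frontier = sub
    step = 1
    while True:
        new = (frontier @ sub) & ~reach
        if not new.any():
            return d
        step += 1
        d[new] = step
        reach |= new
        frontier = new


def nodal_local_efficiency(
    net: BinaryNetwork | np.ndarray, node: int | None = None
) -> np.ndarray | float:
    """Global efficiency of each node's neighbor-induced subgraph.

    Nodes with fewer than two neighbors get 0.
    """
    a = _adj(net)
    if node is None:
        return local_efficiency_kernel(np.ascontiguousarray(a, dtype=np.uint8))
    nb = np.flatnonzero(a[node])
    if nb.size < 2:
        return 0.0
    return _efficiency_from_dist(_subgraph_distances(a[np.ix_(nb, nb)]))


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Network local efficiency: the mean of nodal local efficiency."""
    return float(np.mean(nodal_local_efficiency(net)))


# ---------------------------------------------------------------------------
# null model and small-world normalization


def rewire_preserving_degree(
    net: BinaryNetwork | np.ndarray,
    config: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Degree-preserving randomization by repeated double-edge swaps.

    Attempts ``swaps_per_edge * edge_count`` swaps; a swap replaces edges
    (u,v), (x,y) by (u,y), (v,x) and is rejected if it would create a
    self-loop or a multi-edge.  The output has exactly the input's degree
    sequence.  Deterministic given (adjacency, config.seed); an explicit
    ``rng`` overrides the config seed.
    """
    config = config or NullModelConfig()
    a = np.ascontiguousarray(_adj(net), dtype=np.uint8)
    iu, ju = np.nonzero(np.triu(a, 1))
    m = len(iu)
    if m < 2:
        return a.astype(bool)
    edges = np.stack([iu, ju], axis=1).astype(np.int64)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_attempt = config.swaps_per_edge * m
    ai = rng.integers(0, m, size=n_attempt)
    bi = rng.integers(0, m, size=n_attempt)
    flip = rng.random(n_attempt) < 0.5
    double_edge_swap_kernel(a, edges, ai, bi, flip)
    return a.astype(bool)


def smallworld_normalization(
    net: BinaryNetwork | np.ndarray, config: NullModelConfig | None = None
) -> SmallWorldResult:
    """Normalize clustering and path length by degree-matched surrogates.

    gamma = Cp / <Cp_rand>, lambda = Lp / <Lp_rand>, sigma = gamma / lambda,
    where the averages run over ``config.n_random`` rewired surrogates.  The
    result carries a flag that is False when the network (or any surrogate)
    had unreachable pairs, in which case path lengths average reachable
    pairs only.
    """
    config = config or NullModelConfig()
    a = _adj(net)
    cp = global_clustering(a)
    lp = characteristic_path_length(a)
    rng = np.random.default_rng(config.seed)
    cp_rand = np.empty(config.n_random)
    lp_rand = np.empty(config.n_random)
    all_connected = not lp.disconnected
    for r in range(config.n_random):
        surrogate = rewire_preserving_degree(a, config, rng=rng)
        cp_rand[r] = global_clustering(surrogate)
        res = characteristic_path_length(surrogate)
        lp_rand[r] = res.value
        all_connected &= not res.disconnected
    mean_cp, mean_lp = cp_rand.mean(), lp_rand.mean()
    if mean_cp == 0 or mean_lp == 0:
        raise ValueError("surrogate mean clustering or path length is zero")
    gamma = cp / mean_cp
    lam = lp.value / mean_lp
    return SmallWorldResult(gamma, lam, gamma / lam, all_connected)


# ---------------------------------------------------------------------------
# AUC and per-subject profiles


def auc_over_sparsity(
    values: Sequence[float] | np.ndarray, grid: Sequence[float] | np.ndarray
) -> float:
    """Trapezoidal integral of metric values against the sparsity grid.

    Deliberately *not* normalized by grid width: a metric pinned at 1.0 over
    the default 0.05–0.50 sweep integrates to 0.45.
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape != grid.shape or values.ndim != 1 or len(grid) < 2:
        raise ValueError("values and grid must be 1-D, equal length >= 2")
    return float(np.trapezoid(values, grid))


@dataclass
class GlobalMetricsProfile:
    """Global metrics across a sparsity sweep plus their AUC scalars.

    Arrays are aligned with ``grid``; ``auc`` maps ``aCp, aLp, aEg, aEloc,
    aGamma, aLambda, aSigma`` to scalars.  Normalized metrics are NaN when
    the profile was computed without a null model.
    """

    grid: np.ndarray
    cp: np.ndarray
    lp: np.ndarray
    eg: np.ndarray
    eloc: np.ndarray
    gamma: np.ndarray
    lam: np.ndarray
    sigma: np.ndarray
    disconnected: np.ndarray
    auc: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per (metric, sparsity-or-AUC)."""
        rows = []
        series = dict(
            Cp=self.cp, Lp=self.lp, Eg=self.eg, Eloc=self.eloc,
            Gamma=self.gamma, Lambda=self.lam, Sigma=self.sigma,
        )
        for name, vals in series.items():
            for s, v in zip(self.grid, vals):
                rows.append((name, "global", f"{s:g}", v))
            key = "a" + name
            if key in self.auc:
                rows.append((name, "global", "AUC", self.auc[key]))
        return pd.DataFrame(rows, columns=["metric", "node", "sparsity", "value"])


def subject_profiles(
    networks: Sequence[BinaryNetwork],
    node_labels: Sequence[str] | None = None,
    null_config: NullModelConfig | None = None,
    nodal_metrics: Sequence[str] = NODAL_METRICS,
) -> tuple[GlobalMetricsProfile, "NodalMetricsTable"]:
    """Global and nodal profiles in one pass, sharing distance matrices.

    Each network's all-pairs distance matrix is computed once and reused
    for Lp, Eg, nodal path length and nodal efficiency; the nodal
    clustering vector likewise feeds the global mean.  With
    ``null_config=None`` the normalized metrics (gamma, lambda, sigma) are
    skipped (NaN).
    """
    grid = np.array([net.sparsity for net in networks])
    n_s = len(networks)
    n = networks[0].n_nodes
    labels = tuple(node_labels) if node_labels else tuple(str(i) for i in range(n))
    cp = np.empty(n_s)
    lp = np.empty(n_s)
    eg = np.empty(n_s)
    eloc = np.empty(n_s)
    gamma = np.full(n_s, np.nan)
    lam = np.full(n_s, np.nan)
    sigma = np.full(n_s, np.nan)
    disc = np.zeros(n_s, dtype=bool)
    nodal = {m: np.empty((n, n_s)) for m in nodal_metrics}
    off = ~np.eye(n, dtype=bool)
    for i, net in enumerate(networks):
        ci = nodal_clustering(net)
        cp[i] = ci.mean()
        d = shortest_path_lengths(net)
        finite = np.isfinite(d) & off
        n_reach = finite.sum()
        if n_reach == 0:
            raise ValueError("graph has no edges; path metrics undefined")
        lp[i] = d[finite].sum() / n_reach
        disc[i] = n_reach < n * (n - 1)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        eg[i] = inv.sum() / (n * (n - 1))
        le = nodal_local_efficiency(net)
        eloc[i] = le.mean()
        for m in nodal_metrics:
            if m == "clustering":
                nodal[m][:, i] = ci
            elif m == "degree":
                nodal[m][:, i] = degree_centrality(net)
            elif m == "efficiency":
                nodal[m][:, i] = inv.sum(axis=1) / (n - 1)
            elif m == "local_efficiency":
                nodal[m][:, i] = le
            elif m == "path_length":
                counts = finite.sum(axis=1)
                sums = np.where(finite, d, 0.0).sum(axis=1)
                with np.errstate(invalid="ignore"):
                    nodal[m][:, i] = np.where(counts > 0, sums / counts, np.inf)
            else:
                raise ValueError(f"unknown nodal metric {m!r}")
        if null_config is not None:
            sub = NullModelConfig(
                n_random=null_config.n_random,
                swaps_per_edge=null_config.swaps_per_edge,
                seed=null_config.seed + i,
            )
            sw = smallworld_normalization(net, sub)
            gamma[i], lam[i], sigma[i] = sw.gamma, sw.lam, sw.sigma
    auc = {
        "aCp": auc_over_sparsity(cp, grid),
        "aLp": auc_over_sparsity(lp, grid),
        "aEg": auc_over_sparsity(eg, grid),
        "aEloc": auc_over_sparsity(eloc, grid),
    }
    if null_config is not None:
        auc["aGamma"] = auc_over_sparsity(gamma, grid)
        auc["aLambda"] = auc_over_sparsity(lam, grid)
        auc["aSigma"] = auc_over_sparsity(sigma, grid)
    gp = GlobalMetricsProfile(
        grid=grid, cp=cp, lp=lp, eg=eg, eloc=eloc,
        gamma=gamma, lam=lam, sigma=sigma, disconnected=disc, auc=auc,
    )
    nodal_auc = {
        m: np.array([auc_over_sparsity(nodal[m][j], grid) for j in range(n)])
        for m in nodal_metrics
    }
    nt = NodalMetricsTable(grid=grid, node_labels=labels, values=nodal,
                           auc=nodal_auc)
    return gp, nt


def global_profile(
    networks: Sequence[BinaryNetwork],
    null_config: NullModelConfig | None = None,
) -> GlobalMetricsProfile:
    """Global metric profile over a subject's sparsity sweep.

    With ``null_config=None`` the normalized metrics (gamma, lambda, sigma)
    are skipped (NaN) — useful when only the raw metrics are needed.
    """
    gp, _ = subject_profiles(networks, None, null_config, nodal_metrics=())
    return gp


@dataclass
class NodalMetricsTable:
    """Nodal metrics across a sparsity sweep plus per-node AUC scalars.

    ``values[metric]`` is an (n_nodes, n_sparsity) array; ``auc[metric]`` an
    (n_nodes,) vector.  Metrics: clustering, path_length, efficiency,
    local_efficiency, degree.
    """

    grid: np.ndarray
    node_labels: tuple[str, ...]
    values: dict[str, np.ndarray]
    auc: dict[str, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, mat in self.values.items():
            for i, lab in enumerate(self.node_labels):
                for j, s in enumerate(self.grid):
                    rows.append((metric, lab, f"{s:g}", mat[i, j]))
                rows.append((metric, lab, "AUC", self.auc[metric][i]))
        return pd.DataFrame(rows, columns=["metric", "node", "sparsity", "value"])


def nodal_profile(
    networks: Sequence[BinaryNetwork],
    node_labels: Sequence[str] | None = None,
    metrics: Sequence[str] = NODAL_METRICS,
) -> NodalMetricsTable:
    """Nodal metric table over a subject's sparsity sweep.

    Nodal path length can be infinite for isolated nodes at low sparsity;
    its AUC is then infinite too, and downstream tests treat such values as
    missing.
    """
    _, nt = subject_profiles(networks, node_labels, None, nodal_metrics=metrics)
    return nt
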