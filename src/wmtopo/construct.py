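"""Binary network construction from streamline-count matrices.

A subject's anatomical connectivity arrives as a symmetric nonnegative
integer matrix of streamline counts between atlas regions.  Construction
proceeds in two steps:

1. a fixed count threshold removes putative spurious fibers: an entry
   survives only if its streamline count is *strictly greater* than the
   threshold (default 3);
2. sparsity thresholding keeps, for each target sparsity ``S``, exactly
   ``k = floor(S * n(n-1)/2)`` edges — the ``k`` largest surviving counts —
   and binarizes them.

Sweeping sparsity from 0.05 to 0.50 in steps of 0.05 yields ten nested
binary networks per subject; every graph metric downstream is evaluated on
each of them and summarized by its area under the curve over the sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ConstructionConfig",
    "BinaryNetwork",
    "SparsitySaturationWarning",
    "apply_count_threshold",
    "sparsify",
    "sweep_sparsity",
    "is_connected",
    "read_matrix",
    "write_matrix",
]

DEFAULT_GRID: tuple[float, ...] = tuple(round(0.05 * i, 2) for i in range(1, 11))


class SparsitySaturationWarning(UserWarning):
    """Fewer suprathreshold counts than the sparsity target requires."""


@dataclass(frozen=True)
class ConstructionConfig:
    """Parameters of the threshold-then-sparsify construction.

    Parameters
    ----------
    count_threshold
        Streamline-count threshold tau; an entry survives only if
        ``count > tau``.
    sparsity_grid
        Strictly increasing sparsity values, each in (0, 1).
    require_connected
        Record a connectivity flag for every constructed network.
    """

    count_threshold: int = 3
    sparsity_grid: tuple[float, ...] = DEFAULT_GRID
    require_connected: bool = True

    def __post_init__(self) -> None:
        if self.count_threshold < 0:
            raise ValueError("count_threshold must be >= 0")
        grid = tuple(float(s) for s in self.sparsity_grid)
        if len(grid) == 0:
            raise ValueError("sparsity_grid must be non-empty")
        if any(not (0.0 < s < 1.0) for s in grid):
            raise ValueError("sparsity values must lie in (0, 1)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("sparsity values must be strictly increasing")
        object.__setattr__(self, "sparsity_grid", grid)


@dataclass
class BinaryNetwork:
    """Undirected unweighted graph at a given sparsity.

    ``adjacency`` is a symmetric 0/1 ``int8`` matrix with zero diagonal;
    ``connected`` is ``None`` when connectivity was not evaluated.
    """

    adjacency: np.ndarray
    sparsity: float
    edge_count: int = field(init=False)
    connected: bool | None = None
    saturated: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)
        self.edge_count = int(np.triu(self.adjacency, 1).sum())

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def _check_counts(counts: np.ndarray) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("count matrix must be square")
    if not np.array_equal(c, c.T):
        raise ValueError("count matrix must be symmetric")
    if np.any(c < 0):
        raise ValueError("count matrix must be nonnegative")
    return c


def apply_count_threshold(counts: np.ndarray, tau: int = 3) -> np.ndarray:
    """Zero every entry whose streamline count is <= ``tau``.

    Counts strictly greater than ``tau`` are retained unchanged (the edge
    definition is strict: a count exactly equal to the threshold is
    discarded).
    """
    if tau < 0:
        raise ValueError("count threshold must be >= 0")
    c = _check_counts(counts)
    out = np.where(c > tau, c, 0)
    np.fill_diagonal(out, 0)
    return out


def _ranked_edges(masked: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle positive entries ordered by (count desc, i asc, j asc).

    The total order makes sparsified edge sets deterministic and nested
    across the sparsity grid.
    """
    iu, ju = np.triu_indices(masked.shape[0], k=1)
    w = masked[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def sparsify(masked: np.ndarray, sparsity: float) -> BinaryNetwork:
    """Binarize at a target sparsity, keeping the largest surviving counts.

    Exactly ``k = floor(S * n(n-1)/2)`` edges are kept.  Ties at the cutoff
    are broken lexicographically by (i, j) node-index pair, ascending, so the
    edge set is platform independent.  If fewer than ``k`` positive entries
    exist, all positive entries become edges and a
    :class:`SparsitySaturationWarning` is emitted.
    """
    if not (0.0 < sparsity < 1.0):
        raise ValueError("sparsity must lie in (0, 1)")
    masked = _check_counts(masked)
    n = masked.shape[0]
    k = int(np.floor(sparsity * n * (n - 1) / 2))
    iu, ju = _ranked_edges(masked)
    saturated = len(iu) < k
    if saturated:
        warnings.warn(
            f"sparsity {sparsity} asks for {k} edges but only {len(iu)} "
            "suprathreshold counts exist; keeping all of them",
            SparsitySaturationWarning,
            stacklevel=2,
        )
    iu, ju = iu[:k], ju[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu, ju] = 1
    adj[ju, iu] = 1
    return BinaryNetwork(adjacency=adj, sparsity=float(sparsity), saturated=saturated)


def is_connected(net: BinaryNetwork | np.ndarray) -> bool:
    """True iff a single connected component spans all nodes."""
    adj = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return bool(n_comp == 1)


def sweep_sparsity(
    counts: np.ndarray, config: ConstructionConfig | None = None
) -> list[BinaryNetwork]:
    """Construct one binary network per sparsity-grid value, in grid order.

    The networks are nested: the edge set at a lower sparsity is a subset of
    the edge set at any higher sparsity, because edges are drawn from a
    single deterministic ranking of the thresholded counts.
    """
    config = config or ConstructionConfig()
    masked = apply_count_threshold(counts, config.count_threshold)
    nets = [sparsify(masked, s) for s in config.sparsity_grid]
    if config.require_connected:
        for net in nets:
            net.connected = is_connected(net)
    return nets


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a delimited (TSV/CSV) square count matrix, tolerating a header row."""
    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        m = np.loadtxt(path, delimiter=delim)
    except ValueError:
        m = np.loadtxt(path, delimiter=delim, skiprows=1)
    return m


def write_matrix(path: str | Path, matrix: np.ndarray) -> None:
    """Write a matrix as integer TSV."""
    np.savetxt(path, np.asarray(matrix), fmt="%d", delimiter="\t")
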