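from __future__ import annotations

import numpy as np
import pytest

from wmtopo import CohortConfig, generate_cohort


def er_graph(n: int, p: float, seed: int) -> np.ndarray:
    """Symmetric 0/1 Erdős–Rényi adjacency with zero diagonal."""
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


def ring_lattice(n: int, k: int) -> np.ndarray:
    """Ring lattice: each node tied to its k nearest neighbors per side."""
    a = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for step in range(1, k + 1):
            j = (i + step) % n
            a[i, j] = a[j, i] = 1
    return a


@pytest.fixture(scope="session")
def random_graphs() -> list[np.ndarray]:
    """50 small random graphs (n <= 25) spanning sparse to dense regimes,
    including disconnected and near-empty ones."""
    graphs = []
    for s in range(50):
        n = 5 + (s % 21)  # 5..25
        p = 0.08 + 0.9 * ((s * 37) % 50) / 50
        graphs.append(er_graph(n, p, seed=1000 + s))
    return graphs


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """Reduced cohort (30 nodes, 6 per group) for fast pipeline tests."""
    return CohortConfig(
        n_nodes=30,
        n_per_group=6,
        hub_nodes=(0, 5, 10, 15, 20, 25),
        target_nodes=(0, 5, 10),
        seed=11,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under study-design defaults (seed 42)."""
    return generate_cohort(CohortConfig(seed=42))
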