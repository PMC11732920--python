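import numpy as np
import pytest

from cerebgraph import BinaryGraph, CohortConfig, ParcellationSpec


def graph_from_edges(n, edges, labels=None):
    """Build a BinaryGraph from an edge list on nodes 0..n-1."""
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    labels = labels or [f"n{i}" for i in range(n)]
    e = int(adj.sum()) // 2
    cost = 2 * e / (n * (n - 1)) if n > 1 else 0.0
    return BinaryGraph(labels=labels, adjacency=adj, cost=cost)


def random_graph(n, p, rng):
    """Erdős–Rényi adjacency as a BinaryGraph."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1)
    adj = (adj | adj.T).astype(np.int8)
    return graph_from_edges(n, list(zip(*np.nonzero(np.triu(adj, 1)))))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_parcellation():
    return ParcellationSpec("p4", ("roi0", "roi1", "roi2", "roi3"))


@pytest.fixture
def small_config(small_parcellation):
    """Tiny deterministic cohort configuration for fast unit tests."""
    return CohortConfig(
        n_patients=3, n_controls=3, n_volumes=60,
        parcellation=small_parcellation, affected_rois=("roi1",),
        base_correlation=0.5, correlation_spread=0.0, subject_spread=0.0,
        edge_attenuation=0.4, attenuation_subject_sd=0.0, seed=7,
    )
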