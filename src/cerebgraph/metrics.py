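"""Binary-graph measures for functional brain networks.

Implements, from first principles, the six measures used for nodal and
network-level characterisation of thresholded connectivity graphs:

* nodal degree — number of edges incident to a node;
* nodal / network global efficiency — mean inverse shortest-path length,
  with the convention 1/inf = 0 for unreachable pairs;
* local efficiency — global efficiency of the subgraph induced by a node's
  neighbors (Latora–Marchiori convention; 0 with fewer than 2 neighbors);
* betweenness centrality — Brandes accumulation of pair dependencies,
  normalized by (N-1)(N-2)/2, endpoints excluded;
* average path length — mean hop count over *reachable* pairs (graphs
  thresholded at low cost can be disconnected; unreachable pairs are
  excluded rather than poisoning the mean);
* clustering coefficient — triangle fraction 2*T / (k*(k-1)).

All operate on the :class:`~cerebgraph.connectivity.BinaryGraph` adjacency
(symmetric 0/1, zero diagonal). Distances are unweighted hop counts obtained
by breadth-first search.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "shortest_path_lengths",
    "nodal_global_efficiency",
    "network_global_efficiency",
    "local_efficiency",
    "betweenness_centrality",
    "average_path_length",
    "clustering_coefficient",
    "nodal_degree",
    "nodal_metrics_table",
    "NODAL_METRICS",
]

NODAL_METRICS = (
    "degree",
    "global_efficiency",
    "local_efficiency",
    "betweenness",
    "clustering",
)


def _adjacency(graph) -> np.ndarray:
    """Accept a BinaryGraph or a raw 0/1 adjacency array."""
    adj = getattr(graph, "adjacency", graph)
    adj = np.asarray(adj)
    return adj.astype(bool)


def shortest_path_lengths(graph) -> np.ndarray:
    """All-pairs hop-count matrix by multi-source breadth-first search.

    Returns an (N, N) float matrix with 0 on the diagonal and ``np.inf``
    for unreachable pairs.
    """
    adj = _adjacency(graph)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    # Frontier-expansion BFS from all sources at once: reached[s, v] marks
    # nodes already assigned a distance from source s.
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        nxt = (frontier @ adj) & ~reached
        dist[nxt] = d
        reached |= nxt
        frontier = nxt
    return dist


def nodal_degree(graph, node: int | None = None):
    """Number of edges incident to ``node`` (or the full degree vector)."""
    adj = _adjacency(graph)
    deg = adj.sum(axis=1).astype(int)
    return deg if node is None else int(deg[node])


def nodal_global_efficiency(graph, node: int | None = None, *, _dist=None):
    """Mean of 1/d(node, other) over all other nodes; 1/inf counts as 0."""
    dist = shortest_path_lengths(graph) if _dist is None else _dist
    n = dist.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    inv = np.zeros_like(dist)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(dist)
    inv[finite] = 1.0 / dist[finite]
    eff = inv.sum(axis=1) / (n - 1)
    return eff if node is None else float(eff[node])


def network_global_efficiency(graph) -> float:
    """Nodal global efficiency averaged over all nodes."""
    return float(np.mean(nodal_global_efficiency(graph)))


def local_efficiency(graph, node: int | None = None):
    """Global efficiency of the subgraph induced by a node's neighbors.

    Nodes with fewer than 2 neighbors score 0 (no pairs to integrate).
    """
    adj = _adjacency(graph)
    n = adj.shape[0]

    def one(v: int) -> float:
        nbrs = np.flatnonzero(adj[v])
        if nbrs.size < 2:
            return 0.0
        sub = adj[np.ix_(nbrs, nbrs)]
        return network_global_efficiency(sub)

    if node is not None:
        return one(int(node))
    return np.array([one(v) for v in range(n)])


def betweenness_centrality(graph, node: int | None = None):
    """Fraction of all shortest paths passing through a node (Brandes).

    Endpoints are excluded; normalization is by (N-1)(N-2)/2, the number of
    unordered pairs not involving the node, so values lie in [0, 1].
    """
    adj = _adjacency(graph)
    n = adj.shape[0]
    if n < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    neighbors = [np.flatnonzero(adj[v]) for v in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # single-source shortest paths with path counting
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        queue = [s]
        while queue:
            nxt: list[int] = []
            for v in queue:
                order.append(v)
                for w in neighbors[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
            queue = nxt
        # back-propagation of pair dependencies
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair counted twice (once per endpoint as source)
    bc /= 2.0
    bc /= (n - 1) * (n - 2) / 2.0
    return bc if node is None else float(bc[node])


def average_path_length(graph) -> float:
    """Mean hop count over reachable pairs; NaN if no pair is reachable."""
    dist = shortest_path_lengths(graph)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("average path length needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(dist)
    if not finite.any():
        return float("nan")
    return float(dist[finite].mean())


def clustering_coefficient(graph, node: int | None = None):
    """Triangle fraction 2*T(v) / (k(v) * (k(v)-1)); 0 for degree < 2."""
    adj = _adjacency(graph)
    a = adj.astype(float)
    triangles = np.diag(a @ a @ a) / 2.0
    k = a.sum(axis=1)
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 0, triangles / denom, 0.0)
    return cc if node is None else float(cc[node])


def nodal_metrics_table(graph, labels=None) -> pd.DataFrame:
    """All five nodal measures for every node, plus a network summary row.

    Returns a DataFrame indexed by ROI label (plus a ``__network__`` row
    carrying network global efficiency, average path length and mean
    clustering) with columns ``degree, global_efficiency, local_efficiency,
    betweenness, clustering``.
    """
    adj = _adjacency(graph)
    n = adj.shape[0]
    if labels is None:
        labels = list(getattr(graph, "labels", range(n)))
    dist = shortest_path_lengths(adj)
    geff = nodal_global_efficiency(adj, _dist=dist)
    table = pd.DataFrame(
        {
            "degree": nodal_degree(adj).astype(float),
            "global_efficiency": geff,
            "local_efficiency": local_efficiency(adj),
            "betweenness": betweenness_centrality(adj) if n >= 3 else np.zeros(n),
            "clustering": clustering_coefficient(adj),
        },
        index=pd.Index([str(x) for x in labels], name="roi"),
    )
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(dist)
    apl = float(dist[finite].mean()) if finite.any() else float("nan")
    table.loc["__network__"] = [
        float(table["degree"].mean()),
        float(geff.mean()),
        float(table["local_efficiency"].mean()),
        float(table["betweenness"].mean()) if n >= 3 else 0.0,
        float(table["clustering"].mean()),
    ]
    table.attrs["average_path_length"] = apl
    return table
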