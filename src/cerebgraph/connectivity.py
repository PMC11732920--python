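"""ROI-to-ROI correlation matrices and proportional cost thresholding.

Functional connectivity is defined as the Pearson correlation between
denoised ROI time courses. Before graph measures are computed, each
subject's matrix is binarized at a fixed *network cost* (edge density):
only the strongest fraction of the N(N-1)/2 unique pairs is kept, so every
subject's graph has the same number of edges and topology comparisons are
not confounded by overall correlation level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson-correlation matrix with ROI labels."""

    labels: tuple
    weights: np.ndarray

    def __post_init__(self):
        self.labels = tuple(self.labels)
        w = np.asarray(self.weights, dtype=float)
        n = len(self.labels)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} does not match {n} labels")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("diagonal must be exactly 1")
        self.weights = w

    @property
    def n_rois(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.labels), columns=list(self.labels))


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph from proportional thresholding."""

    labels: tuple
    adjacency: np.ndarray
    cost: float = field(default=0.0)

    def __post_init__(self):
        self.labels = tuple(self.labels)
        a = np.asarray(self.adjacency)
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.labels):
            raise ValueError("adjacency shape inconsistent with labels")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self):
        """Edges as (label_a, label_b) pairs, row-major upper triangle."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]


def correlation_matrix(timeseries, labels=None) -> ConnectivityMatrix:
    """Pairwise Pearson correlations of ROI time courses.

    Parameters
    ----------
    timeseries : (n_volumes, n_rois) array or DataFrame
        Denoised ROI signals; if a DataFrame, its columns supply labels.
    labels : sequence of str, optional
        ROI names; defaults to DataFrame columns or integer strings.

    Constant columns cannot be correlated; their rows/columns are set to 0
    with a warning rather than propagating NaN.
    """
    if isinstance(timeseries, pd.DataFrame):
        if labels is None:
            labels = [str(c) for c in timeseries.columns]
        x = timeseries.to_numpy(dtype=float)
    else:
        x = np.asarray(timeseries, dtype=float)
    n_t, n_rois = x.shape
    if labels is None:
        labels = [str(i) for i in range(n_rois)]
    if n_t < 3:
        raise ValueError(f"need at least 3 time points to correlate, got {n_t}")
    sd = x.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.corrcoef(x, rowvar=False)
    if constant.any():
        bad = [labels[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant ROI time courses set to zero correlation: {bad}")
        w[constant, :] = 0.0
        w[:, constant] = 0.0
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(labels=tuple(labels), weights=w)


def proportional_threshold(matrix: ConnectivityMatrix, cost: float = 0.20,
                           rank: str = "signed") -> BinaryGraph:
    """Keep the strongest ``cost`` fraction of connections; binarize.

    The k = round(cost * N(N-1)/2) pairs with the largest weight become
    edges (round half up, so cost 0.20 on 26 nodes keeps exactly 65 of 325
    pairs). Ranking is by signed correlation by default — the convention
    under which "strongest" means most positive; ``rank="absolute"`` ranks
    by magnitude instead. Ties at the cutoff are broken by ascending
    (row, column) index for determinism.
    """
    if not 0.0 < cost <= 1.0:
        raise ValueError(f"cost must be in (0, 1], got {cost}")
    if rank not in ("signed", "absolute"):
        raise ValueError(f"rank must be 'signed' or 'absolute', got {rank!r}")
    n = matrix.n_rois
    e_total = n * (n - 1) // 2
    k = int(np.floor(cost * e_total + 0.5))  # round half up
    iu, ju = np.triu_indices(n, 1)
    w = matrix.weights[iu, ju]
    if rank == "absolute":
        w = np.abs(w)
    # sort by (-weight, i, j): strongest first, ties by ascending pair index
    order = np.lexsort((ju, iu, -w))
    adj = np.zeros((n, n), dtype=np.int8)
    if k == 0:
        warnings.warn("requested cost keeps zero edges; returning empty graph")
    else:
        keep = order[:k]
        adj[iu[keep], ju[keep]] = 1
        adj |= adj.T
    return BinaryGraph(labels=matrix.labels, adjacency=adj, cost=k / e_total)
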