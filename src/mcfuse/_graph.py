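"""Shared KNN-graph and Leiden helpers."""

from __future__ import annotations

import warnings

import igraph as ig
import leidenalg
import numpy as np
from scipy import sparse
from sklearn.neighbors import kneighbors_graph


def knn_graph(coords: np.ndarray, k: int) -> ig.Graph:
    """Symmetrized unweighted k-nearest-neighbor graph."""
    coords = np.asarray(coords, float)
    if k >= coords.shape[0]:
        raise ValueError(f"k_neighbors={k} must be < n_cells={coords.shape[0]}")
    adj = kneighbors_graph(coords, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    return ig.Graph(n=coords.shape[0], edges=edges)


def leiden(graph: ig.Graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
    )
    return np.asarray(part.membership, dtype=np.int64)


def leiden_at_cluster_count(
    graph: ig.Graph,
    target: int,
    seed: int = 0,
    lo: float = 1e-4,
    hi: float = 50.0,
    max_iter: int = 20,
) -> np.ndarray:
    """Bisection on the Leiden resolution to hit a target cluster count.

    Returns the labeling with the nearest achievable count (with a warning)
    if the target is not reached within ``max_iter`` iterations.
    """
    best_labels, best_gap = None, None
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection: resolution spans decades
        labels = leiden(graph, resolution=mid, seed=seed)
        n = int(labels.max()) + 1
        gap = abs(n - target)
        if best_gap is None or gap < best_gap:
            best_labels, best_gap = labels, gap
        if n == target:
            return labels
        if n < target:
            lo = mid
        else:
            hi = mid
    warnings.warn(
        f"could not reach exactly {target} clusters; nearest achieved count differs by {best_gap}",
        stacklevel=2,
    )
    return best_labels
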