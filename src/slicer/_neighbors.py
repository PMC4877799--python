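"""Deterministic k-nearest-neighbor utilities shared across modules.

Neighbors are found on exact pairwise Euclidean distances with ties broken
by ascending point index (stable sort), so every downstream quantity —
neighborhood variance, LLE weights, geodesic paths — is reproducible.
Self-neighbors are always excluded.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    """Dense Euclidean distance matrix with an exact zero diagonal."""
    X = np.asarray(X, dtype=float)
    return squareform(pdist(X))


def knn_indices(D: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors per row of a distance matrix.

    Returns an (n, k) int array; column j holds each point's (j+1)-th
    neighbor. Distance ties resolve to the smaller index (stable sort).
    """
    n = D.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (k={k}, n={n})")
    D = D.copy()
    np.fill_diagonal(D, np.inf)  # exclude self
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def knn_adjacency(D: np.ndarray, k: int, weighted: bool = True) -> scipy.sparse.csr_matrix:
    """Union-symmetrized kNN adjacency: edge i~j if either is a neighbor of the other."""
    n = D.shape[0]
    nbrs = knn_indices(D, k)
    rows = np.repeat(np.arange(n), k)
    cols = nbrs.ravel()
    data = D[rows, cols] if weighted else np.ones(rows.size)
    A = scipy.sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    return A.maximum(A.T)  # union symmetrization; weights are symmetric distances

def is_connected(A: scipy.sparse.csr_matrix) -> bool:
    n_comp, _ = connected_components(A, directed=False)
    return n_comp == 1
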