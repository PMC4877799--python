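"""Locally linear embedding and alpha-hull based neighbor-count selection.

LLE reconstructs each cell from its k nearest neighbors with sum-to-one
barycentric weights, then finds low-dimensional coordinates preserving
those weights. Because a cellular trajectory should embed as a long,
narrow shape rather than an amorphous cloud, the neighbor count k is
chosen automatically by minimising the embedding's "trajectory width":
the area of the alpha-hull of the 2-D embedding divided by the length of
its longest geodesic, with disc radius alpha = l/10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.linalg
from scipy.spatial import Delaunay, QhullError

from ._neighbors import knn_indices, pairwise_distances
from .graph import build_knn_graph, shortest_paths
from .io import ExpressionMatrix

logger = logging.getLogger("slicer")

#: ridge on the local Gram matrix as a fraction of its trace. Required
#: whenever k exceeds the local intrinsic dimension: with exact (zero
#: residual) reconstructions the embedding cost matrix develops a large
#: null space and the bottom eigenvectors become arbitrary. 1e-3 is the
#: long-standing convention for LLE.
GRAM_REGULARIZATION = 1e-3


@dataclass
class Embedding:
    """n x d LLE coordinates, defined up to sign/rotation of each axis."""

    coords: np.ndarray
    cell_ids: list[str]
    k_used: int
    d: int


@dataclass
class ReconstructionWeights:
    """Sparse n x n barycentric weight matrix W.

    Row i is supported on cell i's k nearest neighbors and sums to 1
    (translational invariance); the diagonal is zero.
    """

    weights: scipy.sparse.csr_matrix
    k: int


@dataclass
class WidthProfile:
    """Per-k trajectory-width records from :func:`select_k`.

    Each record holds (k, longest geodesic l, alpha-hull area a, width w = a/l);
    ``selected_k`` attains the minimum width (ties -> smallest k). Failed k
    values are kept separately with the failure reason.
    """

    records: list[tuple[int, float, float, float]]
    selected_k: int
    failures: list[tuple[int, str]]


def lle_weights(E: ExpressionMatrix | np.ndarray, k: int) -> ReconstructionWeights:
    """Solve the constrained least-squares reconstruction weights.

    For each cell i, minimises |x_i - sum_j w_ij x_j|^2 over its k nearest
    Euclidean neighbors subject to sum_j w_ij = 1, via the closed-form
    Lagrange solution with a trace-scaled ridge on the local Gram matrix
    (so the solve stays conditioned when k exceeds the local intrinsic
    dimension or neighbors coincide).
    """
    X = E.values if isinstance(E, ExpressionMatrix) else np.asarray(E, dtype=float)
    n = X.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (k={k}, n={n})")
    nbrs = knn_indices(pairwise_distances(X), k)
    W = np.zeros((n, k))
    ones = np.ones(k)
    eye = np.eye(k)
    for i in range(n):
        Z = X[nbrs[i]] - X[i]  # k x m, neighbors centered on the point
        G = Z @ Z.T
        trace = np.trace(G)
        if trace > 0:
            G = G + eye * (GRAM_REGULARIZATION * trace)
            w = scipy.linalg.solve(G, ones, assume_a="pos")
        else:  # all neighbors coincide with the point
            w = ones.copy()
        W[i] = w / w.sum()
    rows = np.repeat(np.arange(n), k)
    mat = scipy.sparse.coo_matrix((W.ravel(), (rows, nbrs.ravel())), shape=(n, n)).tocsr()
    return ReconstructionWeights(mat, k)


def lle_embed(E: ExpressionMatrix | np.ndarray, k: int, d: int = 2,
              weights: ReconstructionWeights | None = None) -> Embedding:
    """Standard LLE: bottom non-constant eigenvectors of M = (I-W)^T (I-W).

    Returns the d eigenvectors with smallest nonzero eigenvalue as columns
    (unit norm, as is conventional), skipping the constant bottom
    eigenvector. Coordinates are defined only up to sign and rotation;
    compare geometry-invariant quantities, never raw values.
    """
    X = E.values if isinstance(E, ExpressionMatrix) else np.asarray(E, dtype=float)
    cell_ids = E.cell_ids if isinstance(E, ExpressionMatrix) else [str(i) for i in range(len(X))]
    n = X.shape[0]
    if d < 1:
        raise ValueError("d must be >= 1")
    if weights is None:
        weights = lle_weights(X, k)
    W = weights.weights
    IW = scipy.sparse.identity(n, format="csr") - W
    M = (IW.T @ IW).toarray()
    try:
        # bottom d+1 eigenpairs; index 0 is the constant vector (eigenvalue ~0)
        vals, vecs = scipy.linalg.eigh(M, subset_by_index=[0, d])
    except scipy.linalg.LinAlgError as exc:
        raise RuntimeError(f"LLE eigen-solver failed: {exc}") from exc
    if not np.all(np.isfinite(vecs)):
        raise RuntimeError("LLE eigen-solver produced non-finite coordinates")
    coords = vecs[:, 1 : d + 1]
    logger.info("lle_embed: n=%d, k=%d, d=%d, residual=%.3e", n, k, d, float(vals[1 : d + 1].sum()))
    return Embedding(coords, list(cell_ids), k, d)


def _alpha_complex_area(points: np.ndarray, alpha: float) -> float:
    """Area of the Delaunay alpha-complex: triangles with circumradius <= alpha.

    Collinear/degenerate point sets have zero area by convention (they are
    maximally trajectory-like).
    """
    try:
        tri = Delaunay(points)
    except (QhullError, ValueError):
        return 0.0
    simplices = points[tri.simplices]  # (t, 3, 2)
    a = simplices[:, 1] - simplices[:, 0]
    b = simplices[:, 2] - simplices[:, 0]
    c = simplices[:, 2] - simplices[:, 1]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    area2 = np.abs(cross)  # twice the triangle area
    la, lb, lc = (np.linalg.norm(v, axis=1) for v in (a, b, c))
    with np.errstate(divide="ignore", invalid="ignore"):
        circumradius = np.where(area2 > 0, la * lb * lc / (2.0 * area2), np.inf)
    keep = circumradius <= alpha
    return float(np.sum(area2[keep]) / 2.0)


def trajectory_width(L: Embedding, k: int | None = None) -> tuple[float, float, float]:
    """Trajectory width (l, a, w) of a 2-D embedding.

    l is the length of the longest shortest path in the kNN graph built on
    the embedding (graph diameter, approximated by a double sweep: farthest
    cell from cell 0, then farthest from that); a is the alpha-hull area
    with disc radius alpha = l/10; w = a/l. Requires a connected graph.
    """
    if L.d != 2 or L.coords.shape[1] != 2:
        raise ValueError("trajectory width is defined for 2-D embeddings")
    if L.coords.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    k = L.k_used if k is None else k
    G = build_knn_graph(L.coords, k, L.cell_ids)
    P0 = shortest_paths(G, 0)
    if not P0.reachable.all():
        raise ValueError("kNN graph is disconnected; cannot measure trajectory width")
    far = int(np.argmax(P0.distances))
    P1 = shortest_paths(G, far)
    l = float(np.max(P1.distances))
    if l <= 0:
        return 0.0, 0.0, 0.0  # all points coincident
    a = _alpha_complex_area(L.coords, l / 10.0)
    return l, a, a / l


def select_k(E: ExpressionMatrix | np.ndarray, k_grid: list[int] | None = None,
             d: int = 2) -> WidthProfile:
    """Choose k minimising the trajectory width w_k over a grid.

    Defaults to k in {5, 10, ..., 50} capped at n-1. Embedding or width
    failures for individual k are recorded and skipped; ties in width go to
    the smallest k. Only defined for d = 2 (the hull is planar); pick k
    manually for d > 2.
    """
    if d != 2:
        raise ValueError("automatic k selection requires d = 2; specify k explicitly otherwise")
    n = E.n_cells if isinstance(E, ExpressionMatrix) else len(E)
    if k_grid is None:
        k_grid = [k for k in range(5, 51, 5) if k < n]
    if any(k >= n for k in k_grid):
        raise ValueError("every k in k_grid must be < n")
    records: list[tuple[int, float, float, float]] = []
    failures: list[tuple[int, str]] = []
    for k in k_grid:
        try:
            L = lle_embed(E, k, d)
            l, a, w = trajectory_width(L, k)
        except (RuntimeError, ValueError) as exc:
            failures.append((k, str(exc)))
            logger.warning("select_k: k=%d failed (%s)", k, exc)
            continue
        records.append((k, l, a, w))
    if not records:
        raise RuntimeError("embedding failed for every k in the grid")
    widths = np.array([r[3] for r in records])
    selected = records[int(np.argmin(widths))][0]  # argmin takes first -> smallest k on ties
    logger.info("select_k: selected k=%d from %d candidates", selected, len(records))
    return WidthProfile(records, selected, failures)
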