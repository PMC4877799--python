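"""kNN graph construction, geodesic shortest paths, and cell ordering.

Cells are ordered by geodesic distance along a k-nearest-neighbor graph
built in the low-dimensional embedding: the shortest path from a
user-specified start cell to each other cell approximates the geodesic
along the trajectory manifold, and its length is the cell's progress
measure (pseudotime).

Shortest paths are computed by Dijkstra's algorithm with an explicit
deterministic tie rule — among equal-cost paths the predecessor with the
smaller cell index wins. Branch detection consumes the vertex composition
of these paths, so path choice must be reproducible, not just path length.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import connected_components

from ._neighbors import knn_adjacency, pairwise_distances

logger = logging.getLogger("slicer")


@dataclass
class NeighborGraph:
    """Undirected union-symmetrized kNN graph with Euclidean edge weights."""

    adjacency: scipy.sparse.csr_matrix
    cell_ids: list[str]
    k: int

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class GeodesicPathSet:
    """Single-source shortest paths from a start cell.

    ``paths[i]`` is the vertex index sequence (start, ..., i); ``distances[i]``
    the geodesic distance; both are None/inf for unreachable cells.
    ``hops[i]`` is the number of vertices on the path (1 for the start itself).
    """

    start: int
    cell_ids: list[str]
    paths: list[list[int] | None]
    distances: np.ndarray
    predecessors: np.ndarray

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    @property
    def reachable(self) -> np.ndarray:
        return np.isfinite(self.distances)

    @property
    def hops(self) -> np.ndarray:
        return np.array([len(p) if p is not None else 0 for p in self.paths])


@dataclass
class CellOrdering:
    """Cells ranked by ascending geodesic distance (ties by cell index)."""

    cell_ids: list[str]
    cell_index: np.ndarray
    geodesic_distance: np.ndarray
    rank: np.ndarray  # 1..n_reachable, aligned with the sorted lists


def build_knn_graph(coords: np.ndarray, k: int, cell_ids: list[str] | None = None) -> NeighborGraph:
    """Union-symmetrized kNN graph over embedding coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (k={k}, n={n})")
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n)]
    D = pairwise_distances(coords)
    return NeighborGraph(knn_adjacency(D, k), list(cell_ids), k)


def shortest_paths(G: NeighborGraph, start: int | str) -> GeodesicPathSet:
    """Dijkstra single-source shortest paths with predecessor reconstruction.

    ``start`` may be a cell id or an integer index. Unreachable cells get
    infinite distance and no path. Equal-cost relaxations keep the smaller
    predecessor index.
    """
    if isinstance(start, str):
        try:
            s = G.cell_ids.index(start)
        except ValueError:
            raise KeyError(
                f"unknown start cell {start!r}; valid ids include {G.cell_ids[:5]}..."
            ) from None
    else:
        s = int(start)
        if not 0 <= s < G.n:
            raise KeyError(f"start index {s} out of range 0..{G.n - 1}")

    n = G.n
    A = G.adjacency
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=int)
    dist[s] = 0.0
    done = np.zeros(n, dtype=bool)
    heap: list[tuple[float, int]] = [(0.0, s)]
    indptr, indices, data = A.indptr, A.indices, A.data
    while heap:
        du, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for ptr in range(indptr[u], indptr[u + 1]):
            v = indices[ptr]
            if done[v]:
                continue
            alt = du + data[ptr]
            if alt < dist[v]:
                dist[v] = alt
                pred[v] = u
                heapq.heappush(heap, (alt, v))
            elif alt == dist[v] and pred[v] != -1 and u < pred[v]:
                pred[v] = u  # deterministic tie rule

    paths: list[list[int] | None] = []
    for i in range(n):
        if not np.isfinite(dist[i]):
            paths.append(None)
            continue
        p = [i]
        while p[-1] != s:
            p.append(int(pred[p[-1]]))
        paths.append(p[::-1])
    n_unreachable = int(np.sum(~np.isfinite(dist)))
    if n_unreachable:
        logger.warning("%d cells unreachable from start; excluded from ordering", n_unreachable)
    return GeodesicPathSet(s, list(G.cell_ids), paths, dist, pred)


def order_cells(P: GeodesicPathSet) -> CellOrdering:
    """Rank reachable cells by geodesic distance, ties broken by cell index."""
    reach = np.flatnonzero(P.reachable)
    order = reach[np.argsort(P.distances[reach], kind="stable")]
    return CellOrdering(
        cell_ids=[P.cell_ids[i] for i in order],
        cell_index=order,
        geodesic_distance=P.distances[order],
        rank=np.arange(1, len(order) + 1),
    )


def connected_component_clusters(G: NeighborGraph) -> np.ndarray:
    """Per-cell component labels 1..C, numbered by decreasing component size.

    Components of the low-dimensional kNN graph often correspond to distinct
    cell types; callers can subset to chosen components before ordering.
    """
    _, raw = connected_components(G.adjacency, directed=False)
    sizes = np.bincount(raw)
    # stable renumber: larger components first, ties by first appearance
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty_like(order)
    relabel[order] = np.arange(1, len(order) + 1)
    return relabel[raw]


def filter_components(G: NeighborGraph, labels: np.ndarray, keep: list[int]) -> np.ndarray:
    """Boolean mask of cells in the chosen component labels."""
    return np.isin(labels, keep)
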