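"""Branch and bubble detection via geodesic entropy.

Shortest paths along a non-branching trajectory are highly degenerate:
at any hop distance from the start they pass through essentially one cell.
When the trajectory branches, the paths split into distinct vertex sets.
Geodesic entropy quantifies this: at hop position k, count how often each
vertex occupies position k across all start-anchored shortest paths,
normalise to a distribution p_k, and take its Shannon entropy H_k in bits.
H_k >= 1 signals at least two distinct branches; approximately 2^{H_k}
distinct paths exist k vertices from the start.

A bubble is a branch whose arms reconverge downstream: the arms stay
connected through the kNN graph past the branch point, and (for unequal
arm lengths) the shortest paths wrap around the end of the bubble, which
a recursive branch analysis picks up as a second branch marking the
bubble's end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import connected_components

from .graph import GeodesicPathSet, NeighborGraph, shortest_paths

logger = logging.getLogger("slicer")

PRE_BRANCH = 0
UNASSIGNED = -1


@dataclass
class EntropyProfile:
    """Geodesic entropy H_k per hop position k = 1..max_hops.

    ``counts[k-1]`` maps vertex -> number of paths (of hop length >= k)
    passing through it at position k; ``probs`` holds the normalised
    distributions; ``H[k-1]`` their Shannon entropy in bits.
    """

    H: np.ndarray
    counts: list[dict[int, int]]
    probs: list[dict[int, float]]

    @property
    def max_hops(self) -> int:
        return len(self.H)


@dataclass
class BranchCall:
    """Result of branch detection on one path set.

    ``labels`` assigns each cell 0 (pre-branch), 1..B (branch number),
    or -1 (unassigned / unreachable). ``d`` is the first hop with H >= 1,
    ``c`` the last single-vertex hop, ``b = c + 1`` the branch hop.
    """

    detected: bool
    d: int | None = None
    c: int | None = None
    b: int | None = None
    n_branches: int = 0
    distinguishing_points: list[int] = field(default_factory=list)
    labels: np.ndarray | None = None


@dataclass
class BranchTree:
    """Recursive branch structure: one node per analysed cell subset."""

    cells: np.ndarray  # global cell indices of this node
    call: BranchCall
    entropy: EntropyProfile
    paths: GeodesicPathSet
    children: list["BranchTree"] = field(default_factory=list)

    def depth(self) -> int:
        return 1 + max((c.depth() for c in self.children), default=0)


@dataclass
class BubbleCall:
    """Bubble (reconverging branch) detection result."""

    detected: bool
    start_hop: int | None = None
    end_vertex: int | None = None
    end_hop: int | None = None
    arm_cells: dict[int, np.ndarray] = field(default_factory=dict)


def geodesic_entropy(P: GeodesicPathSet) -> EntropyProfile:
    """Entropy of the vertex occupancy distribution at each hop position.

    At hop k only paths of hop length >= k contribute; f_jk counts paths
    with vertex j at position k, p_jk = f_jk / sum_j f_jk, and
    H_k = -sum_j p_jk log2 p_jk (with 0 log 0 = 0).
    """
    paths = [p for p in P.paths if p is not None]
    if not paths:
        raise ValueError("path set is empty")
    max_hops = max(len(p) for p in paths)
    counts: list[dict[int, int]] = []
    probs: list[dict[int, float]] = []
    H = np.zeros(max_hops)
    for k in range(1, max_hops + 1):
        f: dict[int, int] = {}
        for p in paths:
            if len(p) >= k:
                v = p[k - 1]
                f[v] = f.get(v, 0) + 1
        total = sum(f.values())
        pk = {v: c / total for v, c in f.items()}
        counts.append(f)
        probs.append(pk)
        q = np.array(list(pk.values()))
        H[k - 1] = float(-(q * np.log2(q)).sum())
    return EntropyProfile(H, counts, probs)


def assign_branches(P: GeodesicPathSet, call: BranchCall) -> np.ndarray:
    """Per-cell branch labels from a detected call.

    A cell whose path has fewer than b vertices falls before the branch.
    Otherwise the vertex at position b of its path decides: if it is the
    m-th distinguishing point, the cell joins branch m. Paths through a
    non-distinguishing vertex at b are resolved to the branch whose paths
    share the most downstream vertices (positions >= b); cells with no
    overlap, or tied overlap, stay unassigned.
    """
    if not call.detected:
        raise ValueError("assign_branches requires a detected branch call")
    b = call.b
    assert b is not None
    n = P.n
    labels = np.full(n, UNASSIGNED, dtype=int)
    dp_index = {v: m + 1 for m, v in enumerate(call.distinguishing_points)}
    deferred: list[int] = []
    for i, p in enumerate(P.paths):
        if p is None:
            continue
        if len(p) < b:
            labels[i] = PRE_BRANCH
        else:
            m = dp_index.get(p[b - 1])
            if m is not None:
                labels[i] = m
            else:
                deferred.append(i)
    if deferred:
        # vertex pools: all downstream vertices used by each branch's paths
        pools: dict[int, set[int]] = {m: set() for m in dp_index.values()}
        for i, p in enumerate(P.paths):
            if p is not None and labels[i] > 0:
                pools[labels[i]].update(p[b - 1 :])
        for i in deferred:
            tail = set(P.paths[i][b - 1 :])
            overlaps = {m: len(tail & pool) for m, pool in pools.items()}
            best = max(overlaps.values(), default=0)
            winners = [m for m, o in overlaps.items() if o == best]
            if best > 0 and len(winners) == 1:
                labels[i] = winners[0]
    return labels


def detect_branch(H: EntropyProfile, P: GeodesicPathSet, epsilon: float = 0.05,
                  min_branch_size: int = 10) -> BranchCall:
    """Locate the first branch point from an entropy profile.

    d is the smallest hop with H_d >= 1; c is found by decrementing d until
    only one vertex has p > epsilon; b = c + 1 is the branch hop. The
    round(2^{H_d}) vertices with highest p at hop b become distinguishing
    points, one branch each. Branches attracting fewer than
    ``min_branch_size`` cells are discarded (end-of-trajectory fans); if
    fewer than two branches survive, the scan resumes at the next hop with
    H >= 1. Absence of a branch is a valid result, not an error.
    """
    candidates = np.flatnonzero(H.H >= 1.0) + 1  # hop positions
    for d in candidates:
        c = None
        for kk in range(d, 0, -1):
            if sum(1 for p in H.probs[kk - 1].values() if p > epsilon) == 1:
                c = kk
                break
        if c is None:
            continue
        b = c + 1
        if b > H.max_hops:
            continue
        n_branches = max(2, int(round(2.0 ** H.H[d - 1])))
        pb = H.probs[b - 1]
        # highest p at hop b, ties by smaller vertex index
        ranked = sorted(pb.items(), key=lambda kv: (-kv[1], kv[0]))
        dps = [v for v, _ in ranked[:n_branches]]
        call = BranchCall(True, int(d), int(c), int(b), len(dps), dps)
        labels = assign_branches(P, call)
        sizes = {m: int(np.sum(labels == m)) for m in range(1, len(dps) + 1)}
        survivors = [m for m in range(1, len(dps) + 1) if sizes[m] >= min_branch_size]
        if len(survivors) < 2:
            logger.info("detect_branch: candidate at hop %d discarded (branch sizes %s < t=%d)",
                        b, sizes, min_branch_size)
            continue
        if len(survivors) < len(dps):
            # drop small branches, relabel survivors 1..B, re-resolve their cells
            call = BranchCall(True, int(d), int(c), int(b), len(survivors),
                              [dps[m - 1] for m in survivors])
            labels = assign_branches(P, call)
        call.labels = labels
        logger.info("detect_branch: branch at hop b=%d with %d branches (d=%d, c=%d)",
                    call.b, call.n_branches, call.d, call.c)
        return call
    return BranchCall(False)


def _induced_subgraph(G: NeighborGraph, cells: np.ndarray) -> NeighborGraph:
    A = G.adjacency[cells][:, cells].tocsr()
    return NeighborGraph(A, [G.cell_ids[i] for i in cells], G.k)


def recursive_branches(G: NeighborGraph, P: GeodesicPathSet, call: BranchCall,
                       epsilon: float = 0.05, min_branch_size: int = 10,
                       depth_limit: int = 5) -> BranchTree:
    """Unravel multi-level branching by recursing into each detected branch.

    Each branch's cells induce a subgraph of the kNN graph; the branch cell
    closest to the start (smallest parent geodesic distance) seeds a new
    path set, on which entropy and branch detection run again. Disconnected
    branch subgraphs are analysed on their largest component with a warning.
    Recursion stops when no branch is detected or at ``depth_limit``.
    """
    root_cells = np.arange(G.n) if G.n == P.n else None
    if root_cells is None:
        raise ValueError("graph and path set disagree on cell count")
    H = geodesic_entropy(P)
    tree = BranchTree(root_cells, call, H, P)
    if not call.detected or depth_limit <= 1:
        return tree
    assert call.labels is not None
    for m in range(1, call.n_branches + 1):
        cells = np.flatnonzero(call.labels == m)
        if len(cells) < 3:
            continue
        sub = _induced_subgraph(G, cells)
        n_comp, comp = connected_components(sub.adjacency, directed=False)
        if n_comp > 1:
            logger.warning("branch %d subgraph disconnected (%d components); using largest", m, n_comp)
            largest = np.argmax(np.bincount(comp))
            keep = np.flatnonzero(comp == largest)
            cells = cells[keep]
            sub = _induced_subgraph(G, cells)
        # start: branch cell nearest the original start
        start_local = int(np.argmin(P.distances[cells]))
        subP = shortest_paths(sub, start_local)
        subH = geodesic_entropy(subP)
        subcall = detect_branch(subH, subP, epsilon, min_branch_size)
        child = recursive_branches(sub, subP, subcall, epsilon, min_branch_size, depth_limit - 1)
        child.cells = cells  # map back to parent indexing
        tree.children.append(child)
    return tree


def detect_bubble(G: NeighborGraph, P: GeodesicPathSet, tree: BranchTree,
                  margin: int = 10) -> BubbleCall:
    """Decide whether the first-level branches reconverge into a bubble.

    Detected iff some kNN-graph edge joins cells of different first-level
    branches downstream of the branch hop b. Cells within ``margin`` hops
    of b sit at the branch point itself, where the arms are still adjacent
    in any noisy Y-branch, so both edge endpoints must lie at hops
    > b + margin (default: the minimum-branch-size scale t). The bubble's
    end is the second branch found by the recursive analysis (the hop at
    which wrap-around paths split off), or, for arms of exactly equal
    length, the earliest cross-branch edge.
    """
    call = tree.call
    if not call.detected or call.n_branches < 2:
        return BubbleCall(False)
    assert call.labels is not None and call.b is not None
    labels, hops, b = call.labels, P.hops, call.b
    A = G.adjacency.tocoo()
    cross = (
        (labels[A.row] > 0) & (labels[A.col] > 0)
        & (labels[A.row] != labels[A.col])
        & (hops[A.row] > b + margin) & (hops[A.col] > b + margin)
    )
    if not cross.any():
        return BubbleCall(False)
    arms = {m: np.flatnonzero(labels == m) for m in range(1, call.n_branches + 1)}
    # preferred end estimate: the second-level branch found inside an arm
    end_vertex = end_hop = None
    for child in tree.children:
        if child.call.detected and child.call.b is not None:
            # the vertex at the child's branch hop c, in global indexing
            local_c_vertex = None
            for p in child.paths.paths:
                if p is not None and len(p) >= child.call.c:
                    local_c_vertex = p[child.call.c - 1]
                    break
            if local_c_vertex is not None:
                v = int(child.cells[local_c_vertex])
                if end_vertex is None or hops[v] > hops[end_vertex]:
                    end_vertex, end_hop = v, int(hops[v])
    if end_vertex is None:
        # equal-length arms: earliest cross-branch edge marks the junction
        rows, cols = A.row[cross], A.col[cross]
        pair_hops = np.minimum(hops[rows], hops[cols])
        j = int(np.argmin(pair_hops))
        end_vertex = int(rows[j] if hops[rows[j]] <= hops[cols[j]] else cols[j])
        end_hop = int(hops[end_vertex])
    return BubbleCall(True, int(b), end_vertex, end_hop, arms)
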