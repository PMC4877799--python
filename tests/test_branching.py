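import numpy as np
import pytest
import scipy.sparse
from scipy.sparse.csgraph import floyd_warshall

from slicer import (GeodesicPathSet, NeighborGraph, assign_branches,
                    branch_accuracy, branch_labels_as_strings, detect_branch,
                    detect_bubble, geodesic_entropy, infer_trajectory,
                    recursive_branches, shortest_paths, simulate_branching)
from slicer.branching import PRE_BRANCH


def make_path_set(paths, start=0):
    """Hand-built GeodesicPathSet; distances = hop counts (unit edges)."""
    n = max(v for p in paths for v in p) + 1
    full = [None] * n
    dist = np.full(n, np.inf)
    # every vertex on a path owns its (shortest) prefix path, as in Dijkstra
    for p in paths:
        for end in range(len(p)):
            v = p[end]
            if full[v] is None or end + 1 < len(full[v]):
                full[v] = list(p[: end + 1])
                dist[v] = end
    return GeodesicPathSet(start, [str(i) for i in range(n)], full, dist,
                           np.full(n, -1))


def entropy_by_nested_loops(paths):
    """Literal evaluation of the f/p/H formulas, independent of the package."""
    import math
    max_hops = max(len(p) for p in paths)
    H = []
    for k in range(1, max_hops + 1):
        f = {}
        for p in paths:
            if len(p) >= k:
                f[p[k - 1]] = f.get(p[k - 1], 0) + 1
        total = sum(f.values())
        h = 0.0
        for c in f.values():
            pk = c / total
            if pk > 0:
                h -= pk * math.log2(pk)
        H.append(h)
    return np.array(H)


class TestGeodesicEntropy:
    def test_worked_example_8_of_17_vs_9_of_17(self):
        """17 paths split 8/9 between two vertices at one hop: H is the
        entropy of (8/17, 9/17), just below 1 bit."""
        # 7 and 8 leaf paths plus the two hop-2 vertices' own paths: 8 vs 9
        paths = [[0, 1, 3 + i] for i in range(7)] + [[0, 2, 11 + i] for i in range(8)]
        P = make_path_set(paths)
        H = geodesic_entropy(P)
        p2 = H.probs[1]
        assert sorted(p2.values()) == [8 / 17, 9 / 17]
        expected = -(8 / 17) * np.log2(8 / 17) - (9 / 17) * np.log2(9 / 17)
        assert H.H[1] == pytest.approx(expected, abs=1e-12)
        assert round(H.H[1], 0) == 1.0  # ~1 bit, as a branch signature

    def test_degenerate_hop_zero_entropy(self):
        paths = [[0, 1, v] for v in (2, 3, 4, 5)]
        H = geodesic_entropy(make_path_set(paths))
        assert H.H[0] == 0.0  # everyone starts at the start
        assert H.H[1] == 0.0  # all paths share vertex 1
        assert H.H[2] == pytest.approx(2.0)  # four vertices equally used

    @pytest.mark.parametrize("m", [2, 4, 8])
    def test_uniform_distribution_gives_log2_m(self, m):
        paths = [[0, 1 + j] for j in range(m)]
        H = geodesic_entropy(make_path_set(paths))
        assert H.H[1] == pytest.approx(np.log2(m))

    def test_matches_nested_loop_oracle_on_random_path_sets(self, rng):
        for _ in range(20):
            n_paths = int(rng.integers(3, 12))
            paths = []
            next_v = 1
            for _ in range(n_paths):
                length = int(rng.integers(1, 7))
                p = [0]
                for _ in range(length):
                    if rng.uniform() < 0.5 and next_v > 1:
                        p.append(int(rng.integers(1, next_v)))
                    else:
                        p.append(next_v)
                        next_v += 1
                paths.append(p)
            P = make_path_set(paths)
            stored = [p for p in P.paths if p is not None]
            np.testing.assert_allclose(geodesic_entropy(P).H,
                                       entropy_by_nested_loops(stored), atol=1e-12)

    def test_probabilities_normalised_and_bounded(self, rng):
        paths = [[0] + list(range(1 + 5 * i, 1 + 5 * i + int(rng.integers(1, 5))))
                 for i in range(6)]
        H = geodesic_entropy(make_path_set(paths))
        for k, pk in enumerate(H.probs):
            assert sum(pk.values()) == pytest.approx(1.0)
            assert 0 <= H.H[k] <= np.log2(len(pk)) + 1e-12


class TestDetectBranch:
    def test_nonbranching_chain_not_detected(self):
        paths = [list(range(i + 1)) for i in range(1, 20)]
        P = make_path_set(paths)
        call = detect_branch(geodesic_entropy(P), P)
        assert not call.detected

    def test_end_of_trajectory_fan_suppressed(self):
        """A fan of k leaves at the trajectory tip has entropy log2(k) but
        fewer than t cells per side; the size filter must suppress it."""
        stem = list(range(12))
        paths = [stem[: i + 1] for i in range(1, 12)]
        paths += [stem + [12 + j] for j in range(4)]  # 4-leaf fan at the tip
        P = make_path_set(paths)
        H = geodesic_entropy(P)
        assert H.H[12] == pytest.approx(2.0)
        call = detect_branch(H, P, min_branch_size=10)
        assert not call.detected

    def test_two_clean_branches_detected_and_located(self):
        stem = [0, 1, 2]
        paths = []
        a_cells = list(range(10, 22))
        b_cells = list(range(30, 42))
        for i, c in enumerate(a_cells):
            paths.append(stem + a_cells[: i + 1])
        for i, c in enumerate(b_cells):
            paths.append(stem + b_cells[: i + 1])
        P = make_path_set(paths)
        H = geodesic_entropy(P)
        call = detect_branch(H, P, min_branch_size=10)
        assert call.detected
        assert call.c == 3 and call.b == 4
        assert call.n_branches == 2
        assert set(call.distinguishing_points) == {10, 30}
        labels = call.labels
        assert all(labels[c] == labels[a_cells[0]] for c in a_cells)
        assert all(labels[c] == labels[b_cells[0]] for c in b_cells)
        assert labels[0] == PRE_BRANCH and labels[2] == PRE_BRANCH

    def test_start_cell_is_pre_branch(self):
        paths = [[0] + list(range(1, 1 + i)) for i in range(1, 15)]
        paths += [[0] + list(range(20, 20 + i)) for i in range(1, 15)]
        P = make_path_set(paths)
        call = detect_branch(geodesic_entropy(P), P)
        assert call.detected
        assert call.labels[0] == PRE_BRANCH

    def test_information_interpretation_at_d(self):
        a, b = [10, 11, 12], [20, 21, 22]
        paths = [[0] + arm[: i + 1] for arm in (a, b) for i in range(3)]
        P = make_path_set(paths)
        H = geodesic_entropy(P)
        call = detect_branch(H, P, min_branch_size=2)
        assert call.detected
        assert round(2.0 ** H.H[call.d - 1]) >= 2


@pytest.fixture(scope="module")
def single_branch_run():
    sim = simulate_branching("single_branch", 300, sigma=0.5, p=0.0, seed=1)
    res = infer_trajectory(sim.expression, int(np.argmin(sim.true_t)))
    return sim, res


@pytest.fixture(scope="module")
def bubble_run():
    sim = simulate_branching("bubble", 300, sigma=0.5, p=0.0, seed=1)
    res = infer_trajectory(sim.expression, int(np.argmin(sim.true_t)))
    return sim, res


class TestSimulatedBranching:
    def test_single_branch_found_and_accurate(self, single_branch_run):
        sim, res = single_branch_run
        assert res.branches.detected
        assert res.branches.n_branches == 2
        pred = branch_labels_as_strings(res.branches, len(sim.true_t))
        post = np.isin(sim.true_branch, ["branch_1", "branch_2"])
        assert branch_accuracy(pred[post], sim.true_branch[post]) >= 95.0

    def test_single_branch_is_not_a_bubble(self, single_branch_run):
        _, res = single_branch_run
        assert not res.bubble.detected

    def test_bubble_arms_separated(self, bubble_run):
        sim, res = bubble_run
        assert res.branches.detected and res.branches.n_branches == 2
        pred = branch_labels_as_strings(res.branches, len(sim.true_t))
        arms = np.isin(sim.true_branch, ["arm_1", "arm_2"])
        assert branch_accuracy(pred[arms], sim.true_branch[arms]) >= 90.0

    def test_bubble_detected_with_entropy_signature(self, bubble_run):
        """Entropy spikes above 1 at the branch, drops, and spikes again in
        the recursive profile of an arm (wrap-around past the bubble end)."""
        sim, res = bubble_run
        assert res.bubble.detected
        H = res.entropy.H
        first = int(np.argmax(H >= 1.0))
        assert H[first] >= 1.0
        assert np.any(H[first:] < 1.0)  # the drop after the spike
        assert any(c.call.detected for c in res.tree.children)  # second spike

    def test_bubble_end_near_true_reconvergence(self, bubble_run):
        from scipy.sparse.csgraph import dijkstra
        sim, res = bubble_run
        hops = dijkstra((res.graph.adjacency > 0).astype(float), directed=False,
                        indices=res.bubble.end_vertex, unweighted=True)
        merge_zone = np.flatnonzero(np.abs(sim.true_t - 60.0) <= 0.5)
        assert hops[merge_zone].min() <= 5

    def test_branch_labels_partition_reachable_cells(self, bubble_run):
        sim, res = bubble_run
        labels = res.branches.labels
        reach = res.paths.reachable
        assert np.all(labels[reach] >= -1)
        unassigned = np.mean(labels[reach] == -1)
        assert unassigned < 0.05

    def test_nonbranching_tree_is_single_leaf(self):
        from slicer import simulate_trajectory
        sim = simulate_trajectory(300, sigma=0.5, p=0.0, seed=1)
        res = infer_trajectory(sim.expression, int(np.argmin(sim.true_t)))
        assert not res.branches.detected
        assert res.tree.children == []


class TestBubbleOnCycle:
    def test_pure_loop_is_a_bubble(self):
        """13-node cycle from the start: both arms nonempty, reconvergence
        detected; distances validated against the all-pairs oracle."""
        n = 13
        rows = np.arange(n)
        cols = (rows + 1) % n
        A = scipy.sparse.coo_matrix(
            (np.ones(n), (rows, cols)), shape=(n, n)).tocsr()
        A = A.maximum(A.T)
        G = NeighborGraph(A, [str(i) for i in range(n)], 2)
        P = shortest_paths(G, 0)
        oracle = floyd_warshall(A, directed=False)[0]
        np.testing.assert_allclose(P.distances, oracle)
        H = geodesic_entropy(P)
        call = detect_branch(H, P, min_branch_size=3)
        assert call.detected
        tree = recursive_branches(G, P, call, min_branch_size=3)
        bubble = detect_bubble(G, P, tree, margin=2)
        assert bubble.detected
        assert all(len(v) > 0 for v in bubble.arm_cells.values())


class TestAssignBranches:
    def test_direct_distinguishing_point_rule(self):
        paths = [[0, 1]] + [[0, 1, 2 + 10 * a, 3 + 10 * a + i]
                            for a in (0, 1) for i in range(11)]
        P = make_path_set(paths)
        call = detect_branch(geodesic_entropy(P), P, min_branch_size=5)
        assert call.detected and call.b == 3
        labels = assign_branches(P, call)
        # cells reached through distinguishing point 12 share a label,
        # distinct from those through point 2
        assert labels[12] != labels[2]
        assert labels[1] == PRE_BRANCH

    def test_requires_detected_call(self):
        P = make_path_set([[0, 1], [0, 1, 2]])
        from slicer import BranchCall
        with pytest.raises(ValueError):
            assign_branches(P, BranchCall(False))
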