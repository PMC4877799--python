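"""Synthetic trajectories with known process time, branches, and bubbles.

Expression is simulated as deterministic functions of a latent process
time t plus Gaussian noise: five "pathway" families of functions share a
common dependence on t (analogous to co-regulated genes), each gene gets
a multiplicative factor c ~ N(1, 0.01) and per-cell noise eps ~ N(0, s^2).
Irrelevant genes are made by permuting a simulated gene's values across
cells, destroying the relationship with t while preserving the value
range exactly; genes are reshuffled in groups of five (one per pathway)
with probability p per group.

Branching and bubble topologies place cells on a latent 2-D skeleton
(progression x, arm offset y) and generate three gene families as
functions of (x, y); a bubble's arms carry unequal offsets so one side is
geodesically shorter, which makes the shortest paths wrap around the
bubble's end — the signature the branch detector exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

#: default process-time grid: 801 values 0, 0.1, ..., 80
DEFAULT_T = np.round(np.arange(0, 80.05, 0.1), 10)


@dataclass
class SimulatedTrajectory:
    """Simulated expression with full ground truth."""

    expression: ExpressionMatrix
    true_t: np.ndarray
    reshuffled_mask: np.ndarray  # per-gene: True if relationship with t destroyed
    true_branch: np.ndarray  # per-cell string labels; all "trunk" when linear
    family_assignment: np.ndarray  # per-gene function family id
    sigma: float
    p: float


def _family_functions(family_set: str):
    if family_set == "curved":
        return [
            lambda t, c: 5 * c * np.cos(t / 5) + 8,
            lambda t, c: 5 * c * np.sin(t / 5) + 8,
            lambda t, c: c * np.sqrt(t),
            lambda t, c: 0.5 * c * (t / 20) ** 2,
            lambda t, c: 0.25 * c * (16 - (t / 20) ** 2),
        ]
    if family_set == "mild":
        return [
            lambda t, c: c * (t / 5) + 8,
            lambda t, c: 5 * np.log(t + 1) + 8,  # printed without a c factor
            lambda t, c: c * np.sqrt(t),
            lambda t, c: 0.5 * c * (t / 20) ** 2,
            lambda t, c: 0.25 * c * (16 - (t / 20) ** 2),
        ]
    raise ValueError(f"unknown family_set {family_set!r}")


def simulate_trajectory(n_genes: int = 500, sigma: float = 2.0, p: float = 0.0,
                        family_set: str = "curved", seed: int = 0,
                        t: np.ndarray | None = None,
                        c_sd: float = 0.1) -> SimulatedTrajectory:
    """Simulate a non-branching trajectory of n cells x n_genes.

    Genes cycle through the five function families; each gene g is
    f_fam(t) * c_g + eps with c_g ~ N(1, 0.01) and eps ~ N(0, sigma^2) per
    cell. Groups of five genes (one per family) are reshuffled across
    cells with probability p, recorded in ``reshuffled_mask``. Values are
    on an arbitrary log-like scale and tagged accordingly.

    ``c_sd`` is the standard deviation of the multiplicative factor
    (default 0.1, i.e. c ~ N(1, 0.01)); set it to 0 to force c = 1, which
    makes the noiseless (sigma = 0) output exactly closed-form.
    """
    if n_genes % 5 != 0:
        raise ValueError("n_genes must be divisible by 5 (one gene per pathway per group)")
    rng = np.random.default_rng(seed)
    t = DEFAULT_T.copy() if t is None else np.asarray(t, dtype=float)
    n = len(t)
    fams = _family_functions(family_set)
    family = np.arange(n_genes) % 5
    c = rng.normal(1.0, c_sd, size=n_genes) if c_sd > 0 else np.ones(n_genes)
    X = np.empty((n, n_genes))
    for g in range(n_genes):
        X[:, g] = fams[family[g]](t, c[g])
    X += rng.normal(0.0, sigma, size=X.shape)
    mask = np.zeros(n_genes, dtype=bool)
    for start in range(0, n_genes, 5):  # groups ascending, fixed randomness order
        if rng.uniform() < p:
            for g in range(start, start + 5):
                X[:, g] = X[rng.permutation(n), g]
            mask[start : start + 5] = True
    E = ExpressionMatrix(
        X,
        cell_ids=[f"cell_{i}" for i in range(n)],
        gene_ids=[f"gene_{g}" for g in range(n_genes)],
        space="log",
    )
    return SimulatedTrajectory(E, t, mask, np.full(n, "trunk", dtype=object), family, sigma, p)


def simulate_branching(topology: str = "single_branch", n_genes: int = 300,
                       sigma: float = 0.5, p: float = 0.0, seed: int = 0,
                       t: np.ndarray | None = None) -> SimulatedTrajectory:
    """Simulate a branching or bubble topology with three gene families.

    A latent skeleton drives expression: x = t/10 is progression and y an
    arm-dependent offset. For ``single_branch`` the arms diverge linearly
    after t = 40 and never rejoin (labels trunk/branch_1/branch_2). For
    ``bubble`` the offset is a half-sine bump on t in (20, 60) with
    amplitudes 2.0 vs 1.2 — arms of unequal geodesic length that reconverge
    (labels trunk/arm_1/arm_2/post_bubble). Cells past the split are
    assigned to arms at random. Families: y-sensitive, mixed, and pure
    progression; each gene is family(x, y) * c + eps as in
    :func:`simulate_trajectory`, with the same group-of-three reshuffling
    controlled by p.
    """
    if topology not in {"single_branch", "bubble"}:
        raise ValueError(f"unknown topology {topology!r}")
    if n_genes % 3 != 0:
        raise ValueError("n_genes must be divisible by 3 (one gene per family per group)")
    rng = np.random.default_rng(seed)
    t = DEFAULT_T.copy() if t is None else np.asarray(t, dtype=float)
    n = len(t)
    x = t / 10.0

    arm = np.zeros(n, dtype=int)  # 0 = common path, 1/2 = arms
    labels = np.full(n, "trunk", dtype=object)
    y = np.zeros(n)
    # opposite signs, unequal magnitudes; sqrt-shaped onset so the arms
    # separate decisively right after the split instead of fading apart
    amp = {1: 3.0, 2: -1.8}
    if topology == "single_branch":
        split = 40.0
        post = t > split
        arm[post] = rng.integers(1, 3, size=post.sum())
        ramp = np.sqrt(np.clip(t - split, 0, None) / 5.0)
        for a in (1, 2):
            sel = arm == a
            y[sel] = amp[a] * ramp[sel]
            labels[sel] = f"branch_{a}"
    else:  # bubble
        t0, t1 = 20.0, 60.0
        inside = (t > t0) & (t < t1)
        arm[inside] = rng.integers(1, 3, size=inside.sum())
        bump = np.sqrt(np.clip(np.sin(np.pi * (t - t0) / (t1 - t0)), 0, None))
        for a in (1, 2):
            sel = arm == a
            y[sel] = amp[a] * bump[sel]
            labels[sel] = f"arm_{a}"
        labels[t >= t1] = "post_bubble"

    families = [
        lambda x, y, c: c * (4.0 + y),            # diverges between arms
        lambda x, y, c: c * (4.0 - 0.5 * y + 0.25 * x),  # mixed response
        lambda x, y, c: c * x,                     # pure progression
    ]
    family = np.arange(n_genes) % 3
    c = rng.normal(1.0, np.sqrt(0.01), size=n_genes)
    X = np.empty((n, n_genes))
    for g in range(n_genes):
        X[:, g] = families[family[g]](x, y, c[g])
    X += rng.normal(0.0, sigma, size=X.shape)
    mask = np.zeros(n_genes, dtype=bool)
    for start in range(0, n_genes, 3):
        if rng.uniform() < p:
            for g in range(start, start + 3):
                X[:, g] = X[rng.permutation(n), g]
            mask[start : start + 3] = True
    E = ExpressionMatrix(
        X,
        cell_ids=[f"cell_{i}" for i in range(n)],
        gene_ids=[f"gene_{g}" for g in range(n_genes)],
        space="log",
    )
    return SimulatedTrajectory(E, t, mask, labels, family, sigma, p)


def percent_sortedness(predicted_order: np.ndarray, true_t: np.ndarray) -> float:
    """(1 - s / C(n,2)) x 100 where s counts out-of-order pairs.

    ``predicted_order`` lists cell indices from first to last in the
    inferred ordering; ``true_t`` is indexed by cell. A pair is out of
    order when the earlier-ranked cell has strictly larger true t; ties in
    true t are concordant. 100% = perfectly sorted, 0% = fully reversed.
    """
    order = np.asarray(predicted_order)
    tt = np.asarray(true_t, dtype=float)
    if order.ndim != 1 or len(order) < 2:
        raise ValueError("need an ordering of at least 2 cells")
    if order.max() >= len(tt) or order.min() < 0:
        raise ValueError("ordering refers to cells outside true_t")
    if len(np.unique(order)) != len(order):
        raise ValueError("ordering contains duplicate cells")
    seq = tt[order]
    s = _count_inversions(seq)
    n = len(seq)
    return (1.0 - s / (n * (n - 1) / 2)) * 100.0


def _count_inversions(seq: np.ndarray) -> int:
    """Strict inversions via merge sort, O(n log n); ties are concordant."""
    seq = np.asarray(seq, dtype=float)

    def rec(a: np.ndarray) -> tuple[np.ndarray, int]:
        if len(a) <= 1:
            return a, 0
        mid = len(a) // 2
        left, il = rec(a[:mid])
        right, ir = rec(a[mid:])
        merged = np.empty(len(a))
        inv = il + ir
        i = j = k = 0
        while i < len(left) and j < len(right):
            if left[i] <= right[j]:
                merged[k] = left[i]
                i += 1
            else:
                merged[k] = right[j]
                inv += len(left) - i
                j += 1
            k += 1
        merged[k:] = left[i:] if i < len(left) else right[j:]
        return merged, inv

    return rec(seq)[1]


def directional_sortedness(predicted_order: np.ndarray, true_t: np.ndarray) -> tuple[float, float]:
    """(as-printed, direction-agnostic) sortedness pair.

    The start cell fixes the orientation of an unsupervised ordering
    arbitrarily, so max(v, 100 - v) is reported alongside the raw value.
    """
    v = percent_sortedness(predicted_order, true_t)
    return v, max(v, 100.0 - v)


def branch_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Percent of cells on the correct branch under best label matching.

    Label vocabularies may differ; the bijective matching between predicted
    and true labels maximising agreement is found by the Hungarian
    algorithm. Unassigned cells (predicted label -1 or "unassigned") always
    count as incorrect.
    """
    from scipy.optimize import linear_sum_assignment

    pred = np.asarray(predicted)
    tru = np.asarray(truth)
    if pred.shape != tru.shape:
        raise ValueError("label vectors differ in length")
    assignable = ~np.isin(pred.astype(str), ["-1", "unassigned"])
    p_labels = np.unique(pred[assignable]).tolist()
    t_labels = np.unique(tru).tolist()
    C = np.zeros((len(p_labels), len(t_labels)))
    for i, pl in enumerate(p_labels):
        for j, tl in enumerate(t_labels):
            C[i, j] = np.sum(assignable & (pred == pl) & (tru == tl))
    rows, cols = linear_sum_assignment(-C)
    return float(C[rows, cols].sum() / len(tru) * 100.0)
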