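# Methods

## Model and assumptions

The package assumes the cells in an expression matrix differ mainly in how
far they have progressed through a single sequential process, so that in
gene-expression space they sample a one-dimensional (possibly branching or
looping) manifold — a trajectory. Reconstruction proceeds in stages: select
the genes that vary smoothly along the manifold, embed the cells
nonlinearly into d dimensions, approximate manifold geodesics by shortest
paths in a k-nearest-neighbor graph, and read branching structure out of
the degeneracy of those paths. The method is unsupervised throughout: no
marker genes, no time-point labels, no user-supplied branch count. The one
required user input is the start cell, which fixes the origin and
orientation of pseudotime; an unsupervised ordering cannot determine its
own direction.

All neighbor searches use exact Euclidean distances with ties broken by
ascending cell index (stable sort), and every kNN graph is symmetrized by
edge union (i–j connected if either is among the other's k nearest). Union
symmetrization improves the connectivity of sparse, elongated point sets,
which trajectories are by construction.

## Gene selection

A gene involved in the process changes gradually along the trajectory, so
its differences between neighboring cells are small relative to its spread
over all cells; an uninvolved gene fluctuates as much locally as globally.
The neighborhood variance

S²⁽ᴺ⁾_g = 1/(n·k_c − 1) Σᵢ Σ_{j≤k_c} (e_ig − e_N(i,j),g)²

is a sample variance taken against each cell's k_c nearest neighbors
instead of the mean. Genes with sample variance strictly greater than
S²⁽ᴺ⁾_g are kept. The neighbor count k_c is not free: it is the minimum k
for which the cell kNN graph is connected, found by incrementing k from 1
(linear scan; adequate for the few-thousand-cell inputs this tool targets).
Neighbors are computed in whatever expression space is passed in; the
recommended pipeline log-transforms raw data first (log2(x+1) — the base
and pseudocount only rescale a monotone transform and do not change
neighbor structure).

Permuting a gene's values across cells preserves its sample variance
exactly while destroying local smoothness, which is why the strict
inequality cleanly rejects shuffled genes; this is also the basis of the
simulator's irrelevant-gene model.

## Locally linear embedding

Barycentric reconstruction weights for each cell over its k nearest
neighbors are the closed-form Lagrange solution of the constrained least
squares problem, with a ridge on the local Gram matrix scaled to 1e-3 of
its trace. The ridge is not cosmetic: whenever k exceeds the local
intrinsic dimension the reconstruction residual is exactly zero, the
embedding cost matrix (I−W)ᵀ(I−W) develops a null space of dimension
greater than d+1, and its bottom eigenvectors — the coordinates — become
arbitrary. The 1e-3 scale is the long-standing LLE convention; markedly
weaker ridges (1e-5 and below) empirically collapse the geodesic ordering
of noiseless simulated curves from 100% to near-chance sortedness. A side
effect worth knowing: a neighbor that reconstructs a point exactly (e.g. a
duplicate cell) receives weight 1 − O(1e-3), not 1 to machine precision.

Coordinates are the d bottom non-constant eigenvectors of (I−W)ᵀ(I−W)
(unit norm, as is conventional), so the sum of retained eigenvalues equals
the embedding-space reconstruction residual. Coordinates are defined only
up to sign and rotation; all downstream computation and all tests use
geometry-invariant quantities (distances, graphs, orderings).

## Choosing k

For each k in a grid (default 5, 10, …, 50, capped at n−1), the cells are
embedded and the embedding's trajectory width w_k = a/l is measured: l is
the longest shortest-path length in the kNN graph on the embedding, a the
area of the α-hull of the 2-D points with disc radius α = l/10. The α-hull
area is computed as the Delaunay α-complex — the sum of areas of Delaunay
triangles whose circumradius is at most α; degenerate (collinear) point
sets get area 0, which correctly marks them as maximally trajectory-like.
Hole areas of pathological point sets are excluded by this construction.
The selected k minimizes w_k, ties to the smaller k; k values whose graph
is disconnected are recorded as failures and skipped.

Because no start cell is known at selection time, l uses a double-sweep
diameter approximation: the farthest cell from an arbitrary cell, then the
farthest cell from that one (two Dijkstra runs, deterministic). Width-based
selection is defined for d = 2, where the hull is planar; for d > 2 the
user supplies k.

## Ordering and branch detection

Shortest paths from the start cell are computed with Dijkstra's algorithm
using an explicit tie rule: among equal-cost paths, the predecessor with
the smaller cell index wins. Branch detection consumes the vertex
composition of the paths, not just their lengths, so path choice must be
deterministic. Unreachable cells (disconnected graph components) are
excluded from the ordering and branch analysis with a warning; the
connected-component clustering utility lets the user subset to components
of interest first.

Geodesic entropy at hop h is the Shannon entropy (bits) of the occupancy
distribution of vertices at position h over all paths of hop length ≥ h.
Detection takes the smallest d with H_d ≥ 1, backtracks to the last hop c
where only one vertex has probability above ε (default 0.05, strict
inequality), sets the branch hop b = c+1, and takes the round(2^{H_d})
highest-probability vertices at hop b (minimum 2) as distinguishing
points. Cells with paths shorter than b hops are pre-branch; a cell whose
path uses distinguishing point m at hop b joins branch m; a cell passing
through a non-distinguishing vertex at b joins the branch whose paths
share the most downstream vertices with its own (ties or no overlap →
unassigned). Branches attracting fewer than t cells (default 10) are
end-of-trajectory artifacts — a fan of k leaf paths at the tip has entropy
log2(k) without any real branch — and are discarded; if fewer than two
branches survive, the scan resumes at the next hop with H ≥ 1.

Recursion: each detected branch's cells induce a subgraph of the kNN
graph (largest component if disconnected, with a warning); the branch cell
nearest the original start seeds a fresh path set, and detection repeats,
to a default depth limit of 5.

Bubbles: if the first-level branches are joined by a kNN edge downstream
of the branch point, the arms reconverge. "Downstream" requires both edge
endpoints more than t hops past b: in any noisy Y-branch the arms are
still adjacent within a few hops of the split, so testing strictly at
hops > b would call every branch a bubble; t is already the method's
resolution scale for spurious structure. With arms of unequal geodesic
length, shortest paths wrap around the bubble's end into the far side of
the longer arm, and the recursive analysis of the branch carrying the
wrap-around detects a second branch whose location is the bubble's end.
(Both branches are recursed, so it does not matter which one carries it.)
For arms of exactly equal length no wrap-around occurs and the end is the
earliest cross-branch edge.

## Synthetic data

The simulator emulates expression driven by a latent process time t over
801 values 0, 0.1, …, 80. Five function families stand in for co-regulated
pathways:

f1 = 5c·cos(t/5) + 8, f2 = 5c·sin(t/5) + 8, f3 = c·√t,
f4 = ½c(t/20)², f5 = ¼c(16 − (t/20)²),

each gene getting its own factor c ~ N(1, 0.01) and per-cell noise
ε ~ N(0, σ²). A "mild" family set replaces f1, f2 with c(t/5) + 8 and
5·log(t+1) + 8 for a less curved manifold. Irrelevant genes are simulated
by permuting whole groups of five genes (one per family) across cells with
probability p per group — permutation keeps each gene's value range exactly
while severing its relation to t. Defaults (500 genes, σ = 2) are the
conditions of the headline ordering experiments; σ = 0.5 with p = 0.5 is
the gene-selection recovery condition. Simulated values live on an
arbitrary log-like scale (they may dip slightly below zero at low-signal
points once noise is added, and are deliberately not clipped), so the
simulator tags its matrices as log-space and the pipeline consumes them
directly without a further transform.

Branching and bubble topologies use three families driven by a latent
(progression, arm-offset) skeleton: x = t/10, and an offset y that is zero
on the trunk and arm-specific afterwards — a sqrt-shaped ramp after the
split at t = 40 for the Y-branch, and a sqrt-sine bump on t ∈ (20, 60) for
the bubble, with amplitudes +3.0 and −1.8 so one side of the bubble is
geodesically shorter and the wrap-around signature appears. The sqrt onset
makes the arms separate decisively right after the split; with a smoothly
fading onset the arms remain inside each other's noise envelope near the
branch point, which is a different geometry from a discrete fate decision.
Families: c(4 + y) (diverging), c(4 − y/2 + x/4) (mixed), c·x (pure
progression); 300 genes and σ = 0.5 are the branch-experiment conditions —
a hard setting, as these functions have a much smaller range than the
f1–f5 set. Cells inside the branching window are assigned to arms
uniformly at random; all randomness flows from one seeded generator with a
fixed consumption order (groups ascending), so equal seeds give
bit-identical output.

What the simulator does *not* emulate: count noise (negative binomial,
dropout), library-size variation, batch effects, or genes with zero
expression — passing tests demonstrate the geometry and algorithmics of
the method, not robustness to scRNA-seq technical artifacts.

Evaluation metrics: percent sortedness is (1 − s/C(n,2))·100 with s the
number of strict inversions of true t under the predicted order (ties in
t are concordant; counted by merge sort). Because orientation is
arbitrary, a direction-agnostic variant max(v, 100−v) is reported
alongside. Branch accuracy is the percentage of cells on the correct
branch under the best bijective matching of predicted to true labels
(Hungarian algorithm); unassigned cells always count as wrong. A uniformly
random ordering of the 801-cell trajectory scores 50% sortedness on
average, tightly peaked — the floor against which reconstructions are
judged.

## Numerical and design choices

- Expression containers enforce: no missing values, unique string ids on
  both axes, non-negative values in raw space, n ≥ 2.
- Cell filtering keeps cells detecting ≥ 1000 genes at ≥ 1 expression unit
  (both configurable); it is idempotent and order-preserving.
- Distance ties, equal-cost paths, equal widths, and equal branch
  probabilities all resolve toward the smaller index/value, making every
  stage deterministic without randomness.
- The ordering kNN graph reuses the LLE k by default (one k throughout);
  callers may override.
- Problem sizes in the shipped tests follow the simulator defaults
  (801 cells; 300–500 genes), the scale the method targets.

## Known limitations

- Gene selection assumes the trajectory dominates the data's geometry; a
  strong confounding structure (cell cycle on top of differentiation)
  will be reflected in the neighbor graph and thus in what "smooth" means.
- Width-based k selection is restricted to d = 2.
- The H ≥ 1 branch threshold is a hard cutoff with no significance model;
  branches carrying very few cells (below t) are undetectable by design.
- The bubble-end locator depends on the arms having unequal geodesic
  lengths (or a clean cross-branch edge for equal arms); heavily noised
  bubbles may report an end several hops from the true reconvergence.
- O(n²) distance matrices cap practical input size at a few thousand
  cells.
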