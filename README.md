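# slicer-trajectory

Branched, nonlinear pseudotime trajectory inference for single-cell RNA-seq,
with automatic gene selection, automatic neighbor-count selection, and
entropy-based branch/bubble detection.

Single-cell RNA-seq gives a set of "snapshots" of cells progressing through
a temporal process (differentiation, activation, the cell cycle) at unknown
and uneven rates. This package reconstructs that progression from the
expression matrix alone — no marker genes, no synchronized time points — for
analysts who want an unsupervised internal clock for their cells, including
processes whose geometry branches toward multiple fates or even loops.

## Method

Given a cells × genes matrix `E` (n cells, m genes, log-scale expression):

1. **Gene selection by neighborhood variance.** For each gene g, compare the
   sample variance σ̂²_g against the neighborhood variance

   S²⁽ᴺ⁾_g = 1/(n·k_c − 1) · Σᵢ Σⱼ (e_ig − e_N(i,j),g)²,

   where N(i, j) is cell i's j-th nearest neighbor and k_c is the smallest
   neighbor count that connects the cell kNN graph. Genes with
   σ̂²_g > S²⁽ᴺ⁾_g vary gradually from cell to cell — the signature of
   involvement in a sequential process — and are kept; genes that fluctuate
   as much locally as globally are dropped.

2. **Locally linear embedding (LLE).** Each cell is reconstructed from its k
   nearest neighbors with sum-to-one barycentric weights
   (argmin_W Σᵢ |Eᵢ − Σⱼ w_ij Eⱼ|², rows of W summing to 1), then
   d-dimensional coordinates L preserving those weights are found from the
   bottom eigenvectors of (I−W)ᵀ(I−W). LLE captures highly nonlinear
   trajectories that a linear projection would fold over.

3. **Automatic choice of k.** A trajectory should embed as a long, narrow
   shape. For each candidate k, the embedding's "width" w_k = a/l is
   computed, where l is the longest geodesic in the embedding's kNN graph
   and a is the area of the α-hull of the 2-D embedding with disc radius
   α = l/10; k = argmin w_k.

4. **Geodesic ordering.** A kNN graph is built in the low-dimensional space
   and Dijkstra shortest paths are computed from a user-chosen start cell;
   cells are ranked by geodesic distance (pseudotime).

5. **Branch detection by geodesic entropy.** At hop position h, count how
   often each vertex occupies position h across all shortest paths,
   normalize to a distribution p_h, and take the Shannon entropy H_h in
   bits. A non-branching trajectory has degenerate paths (H ≈ 0); H_h ≥ 1
   signals ≥ 2 branches, located by backtracking to the last single-vertex
   hop. Each cell is assigned to the branch of the "distinguishing point"
   its path uses at the branch hop. Recursing into each branch unravels
   multi-level structures, and arms that reconnect downstream of the branch
   point are reported as a "bubble" (a loop that closes again).

A synthetic-trajectory simulator (deterministic gene families of a latent
process time plus Gaussian noise, permuted irrelevant genes, branch and
bubble topologies) and the matching evaluation metrics (percent sortedness,
branch accuracy) are included, so the whole method is testable end to end
with known ground truth.

## Worked example

```python
import numpy as np
from slicer import (simulate_branching, infer_trajectory, percent_sortedness,
                    branch_accuracy, branch_labels_as_strings)

sim = simulate_branching("bubble", n_genes=300, sigma=0.5, p=0.0, seed=1)
start = int(np.argmin(sim.true_t))
res = infer_trajectory(sim.expression, start)

print("selected genes:", len(res.genes.selected_gene_ids), "of", sim.expression.n_genes)
print("auto-selected k:", res.embedding.k_used)
v = percent_sortedness(res.ordering.cell_index, sim.true_t)
print("percent sortedness: %.1f%%" % max(v, 100 - v))
print("branch detected at hop b =", res.branches.b,
      "with", res.branches.n_branches, "branches")
pred = branch_labels_as_strings(res.branches, sim.expression.n_cells)
arms = np.isin(sim.true_branch, ["arm_1", "arm_2"])
print("arm assignment accuracy: %.1f%%" % branch_accuracy(pred[arms], sim.true_branch[arms]))
print("bubble detected:", res.bubble.detected,
      "- ends at hop", res.bubble.end_hop,
      "(cell %s, true t = %.1f)" % (res.bubble.end_vertex, sim.true_t[res.bubble.end_vertex]))
```

Output:

```
selected genes: 300 of 300
auto-selected k: 20
percent sortedness: 91.5%
branch detected at hop b = 15 with 2 branches
arm assignment accuracy: 95.7%
bubble detected: True - ends at hop 46 (cell 597, true t = 59.7)
```

The simulation places 801 cells on a trajectory whose two arms split at
process time t = 20 and rejoin at t = 60. The pipeline keeps all 300
(trajectory-relevant) genes, picks k = 20 by the width criterion, orders the
cells at 91.5% agreement with true process time, splits the arms at 95.7%
accuracy, and locates the bubble's end at a cell with true t = 59.7 — right
at the true reconvergence point.

The same pipeline is available from the shell:

```bash
slicer simulate --topology bubble --genes 300 --sigma 0.5 --p 0 --seed 1 --out sim/
slicer select-genes --in sim/matrix.tsv --space log --out genes.txt
slicer embed --in sim/matrix.tsv --space log --genes genes.txt --k auto --out embedding.tsv
slicer order --embedding embedding.tsv --k 20 --start cell_0 --out ordering.tsv
slicer branches --embedding embedding.tsv --k 20 --start cell_0 --out branches.tsv --report report.json
slicer evaluate --ordering ordering.tsv --truth sim/truth.tsv --branches branches.tsv
```

## Documentation

See `docs/methods.md` for the model's assumptions, every tunable parameter
with its default and rationale, what the simulator does and does not
emulate, and known limitations.
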