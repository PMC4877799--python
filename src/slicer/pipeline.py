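"""End-to-end trajectory inference: genes -> embedding -> ordering -> branches."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .branching import BranchCall, BranchTree, BubbleCall, EntropyProfile, detect_branch, \
    detect_bubble, geodesic_entropy, recursive_branches
from .embedding import Embedding, WidthProfile, lle_embed, select_k
from .genes import GeneSelectionResult, select_genes
from .graph import CellOrdering, GeodesicPathSet, NeighborGraph, build_knn_graph, \
    order_cells, shortest_paths
from .io import AnalysisConfig, ExpressionMatrix

logger = logging.getLogger("slicer")


@dataclass
class TrajectoryResult:
    """Everything the pipeline produced, from gene selection to bubbles."""

    genes: GeneSelectionResult | None
    width_profile: WidthProfile | None
    embedding: Embedding
    graph: NeighborGraph
    paths: GeodesicPathSet
    ordering: CellOrdering
    entropy: EntropyProfile
    branches: BranchCall
    tree: BranchTree
    bubble: BubbleCall


def infer_trajectory(E: ExpressionMatrix, start: int | str,
                     config: AnalysisConfig | None = None,
                     gene_selection: bool = True) -> TrajectoryResult:
    """Run the full pipeline on an expression matrix.

    Selects trajectory genes (optional), picks k automatically when
    ``config.k == "auto"`` (d must be 2), embeds with LLE, orders cells by
    geodesic distance from ``start``, and runs the recursive branch and
    bubble analysis.
    """
    cfg = config or AnalysisConfig()
    genes = None
    X = E
    if gene_selection:
        genes = select_genes(E)
        if genes.selected_gene_ids:
            X = E.subset_genes(genes.selected_gene_ids)
        else:
            logger.warning("gene selection returned no genes; using all genes")
    width = None
    if cfg.k == "auto":
        grid = [k for k in cfg.k_grid if k < X.n_cells]
        width = select_k(X, grid, cfg.d)
        k = width.selected_k
    else:
        k = int(cfg.k)
    L = lle_embed(X, k, cfg.d)
    G = build_knn_graph(L.coords, k, L.cell_ids)
    P = shortest_paths(G, start)
    ordering = order_cells(P)
    H = geodesic_entropy(P)
    call = detect_branch(H, P, cfg.epsilon, cfg.min_branch_size)
    tree = recursive_branches(G, P, call, cfg.epsilon, cfg.min_branch_size)
    bubble = detect_bubble(G, P, tree, margin=cfg.min_branch_size)
    return TrajectoryResult(genes, width, L, G, P, ordering, H, call, tree, bubble)


def branch_labels_as_strings(call: BranchCall, n: int) -> np.ndarray:
    """Human-readable labels: pre_branch / branch_m / unassigned."""
    out = np.full(n, "unassigned", dtype=object)
    if call.labels is None:
        return out
    out[call.labels == 0] = "pre_branch"
    for m in range(1, call.n_branches + 1):
        out[call.labels == m] = f"branch_{m}"
    return out
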