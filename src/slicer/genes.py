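"""Unsupervised gene selection by sample vs. neighborhood variance.

A gene that changes gradually along a cellular trajectory varies little
between neighboring cells relative to its spread over the whole dataset;
a gene unrelated to the process fluctuates as much locally as globally.
Comparing the per-gene sample variance with a "neighborhood variance" —
a variance computed against each cell's nearest neighbors instead of the
mean — therefore separates trajectory genes from noise genes without any
marker knowledge or differential-expression pre-analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._neighbors import is_connected, knn_adjacency, knn_indices, pairwise_distances
from .io import ExpressionMatrix

logger = logging.getLogger("slicer")


@dataclass
class GeneSelectionResult:
    """Outcome of :func:`select_genes`.

    ``selected_gene_ids`` is exactly the set of genes whose sample variance
    strictly exceeds their neighborhood variance, in input gene order;
    ``k_c`` is the connectivity neighbor count used for the neighbor lists.
    """

    selected_gene_ids: list[str]
    sample_variance: np.ndarray
    neighborhood_variance: np.ndarray
    k_c: int


def minimum_connected_k(E: ExpressionMatrix) -> int:
    """Smallest k for which the union-symmetrized kNN graph over cells is connected.

    Distances are Euclidean over all genes. Starts at k=1 and increments;
    the answer is at most n-1 (complete graph).
    """
    n = E.n_cells
    if n < 2:
        raise ValueError("need at least 2 cells")
    D = pairwise_distances(E.values)
    for k in range(1, n):
        if is_connected(knn_adjacency(D, k, weighted=False)):
            logger.info("minimum_connected_k: k_c=%d (n=%d)", k, n)
            return k
    return n - 1  # unreachable: complete graph is connected


def neighborhood_variance(E: ExpressionMatrix, k_c: int) -> np.ndarray:
    """Per-gene neighborhood variance S^2_N.

    For gene g with neighbor lists N(i, j) (j-th nearest neighbor of cell i,
    Euclidean over all genes, self excluded):

        S^2_N(g) = 1/(n*k_c - 1) * sum_i sum_{j<=k_c} (e_ig - e_N(i,j),g)^2

    i.e. a sample variance taken with respect to neighboring points rather
    than the mean.
    """
    n = E.n_cells
    if n * k_c <= 1:
        raise ValueError("n * k_c must exceed 1")
    D = pairwise_distances(E.values)
    nbrs = knn_indices(D, k_c)
    V = E.values
    total = np.zeros(E.n_genes)
    for j in range(k_c):
        diff = V - V[nbrs[:, j]]
        total += np.einsum("ij,ij->j", diff, diff)
    return total / (n * k_c - 1)


def select_genes(E: ExpressionMatrix) -> GeneSelectionResult:
    """Select genes with sample variance strictly above neighborhood variance.

    The connectivity neighbor count k_c is determined automatically. Sample
    variance uses the n-1 denominator. Returns an empty selection (with a
    warning) rather than failing when no gene qualifies.
    """
    k_c = minimum_connected_k(E)
    s2 = np.var(E.values, axis=0, ddof=1)
    s2n = neighborhood_variance(E, k_c)
    mask = s2 > s2n
    selected = [g for g, m in zip(E.gene_ids, mask) if m]
    if not selected:
        warnings.warn("no genes selected: sample variance never exceeds neighborhood variance")
    logger.info("select_genes: %d of %d genes selected (k_c=%d)", len(selected), E.n_genes, k_c)
    return GeneSelectionResult(selected, s2, s2n, k_c)
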