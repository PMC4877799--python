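"""Expression-matrix container, readers/writers, cell filtering, log transform.

The internal convention is cells-as-rows: an ``ExpressionMatrix`` holds the
n x m matrix E = (e_ij) with n cells (samples) and m genes. Readers accept
either orientation and normalise on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("slicer")

Orientation = Literal["cells_as_rows", "genes_as_rows"]


class ValidationError(ValueError):
    """Raised when an input matrix violates the container invariants."""


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with string identifiers on both axes.

    Parameters
    ----------
    values
        Dense float array of shape ``(n_cells, n_genes)``; non-negative when
        ``space == "raw"``, unrestricted after log transform.
    cell_ids, gene_ids
        Unique string identifiers aligned with the rows / columns.
    space
        ``"raw"`` for linear-scale units (e.g. FPKM), ``"log"`` after
        :func:`log_transform` (or for data simulated directly on log scale).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    space: Literal["raw", "log"] = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise ValidationError(f"need at least 2 cells and 1 gene, got {n} x {m}")
        if len(self.cell_ids) != n or len(self.gene_ids) != m:
            raise ValidationError("id lengths do not match matrix shape")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != m:
            raise ValidationError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains missing/non-finite values")
        if self.space == "raw" and np.any(self.values < 0):
            raise ValidationError("raw expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        """Row subset preserving order; ``index`` is a boolean mask or int array."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Column subset by gene id, in the given order."""
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in pos]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        cols = [pos[g] for g in gene_ids]
        return replace(
            self,
            values=self.values[:, cols],
            cell_ids=list(self.cell_ids),
            gene_ids=[str(g) for g in gene_ids],
        )


@dataclass
class AnalysisConfig:
    """Tunable parameters of the trajectory pipeline.

    ``k`` is the neighbor count for LLE and the low-dimensional graph
    ("auto" selects it by minimising the alpha-hull trajectory width);
    ``epsilon`` is the probability floor used when backtracking to the last
    pre-branch hop; ``min_branch_size`` (t) suppresses end-of-trajectory fans.
    """

    k: int | str = "auto"
    d: int = 2
    epsilon: float = 0.05
    min_branch_size: int = 10
    detection_threshold: float = 1.0
    min_genes_detected: int = 1000
    k_grid: list[int] = field(default_factory=lambda: list(range(5, 51, 5)))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValidationError("d must be >= 1")
        if not (0 < self.epsilon < 1):
            raise ValidationError("epsilon must lie in (0, 1)")
        if self.min_branch_size < 1:
            raise ValidationError("min_branch_size must be positive")
        if isinstance(self.k, str) and self.k != "auto":
            raise ValidationError("k must be a positive integer or 'auto'")
        if not isinstance(self.k, str) and self.k < 1:
            raise ValidationError("k must be positive")
        if sorted(self.k_grid) != list(self.k_grid) or any(k < 1 for k in self.k_grid):
            raise ValidationError("k_grid must be an ascending list of positive integers")


def _read_id_file(path: Path) -> list[str]:
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def load_expression(path: str | Path, orientation: Orientation = "cells_as_rows",
                    space: Literal["raw", "log"] = "raw") -> ExpressionMatrix:
    """Load an expression matrix from dense TSV/CSV or a MatrixMarket triple.

    Dense input: header row of ids plus a leading id column; the delimiter is
    sniffed from the extension (.tsv -> tab, .csv -> comma). MatrixMarket
    input (.mtx): sidecar files ``<stem>.rownames.txt`` / ``<stem>.colnames.txt``
    hold newline-delimited identifiers.

    ``genes_as_rows`` input is transposed so the result always has cells as
    rows. Pass ``space="log"`` for matrices already on a log-like scale
    (e.g. simulator output), which skips the raw non-negativity check.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = _read_id_file(path.parent / (path.stem + ".rownames.txt"))
        cols = _read_id_file(path.parent / (path.stem + ".colnames.txt"))
        if len(rows) != mat.shape[0] or len(cols) != mat.shape[1]:
            raise ValidationError("sidecar id files do not match matrix dimensions")
        values, cell_ids, gene_ids = np.asarray(mat, dtype=float), rows, cols
    else:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pandas reports the offending line
            raise ValidationError(f"could not parse {path.name}: {exc}") from exc
        if df.shape[1] == 0:
            raise ValidationError(f"{path.name}: no data columns found")
        # pandas silently mangles duplicate header names; check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValidationError(f"{path.name}: duplicate ids in header row")
        values = df.to_numpy(dtype=float)
        cell_ids = [str(i) for i in df.index]
        gene_ids = [str(c) for c in df.columns]
    if orientation == "genes_as_rows":
        values = values.T
        cell_ids, gene_ids = gene_ids, cell_ids
    E = ExpressionMatrix(values, cell_ids, gene_ids, space=space)
    logger.info("loaded %d cells x %d genes from %s", E.n_cells, E.n_genes, path)
    return E


def write_expression(E: ExpressionMatrix, path: str | Path) -> None:
    """Write to dense TSV/CSV (by extension) or a MatrixMarket triple (.mtx)."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(E.values))
        (path.parent / (path.stem + ".rownames.txt")).write_text("\n".join(E.cell_ids) + "\n")
        (path.parent / (path.stem + ".colnames.txt")).write_text("\n".join(E.gene_ids) + "\n")
    else:
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        pd.DataFrame(E.values, index=E.cell_ids, columns=E.gene_ids).to_csv(path, sep=sep)


def filter_cells(E: ExpressionMatrix, min_genes_detected: int = 1000,
                 detection_threshold: float = 1.0) -> ExpressionMatrix:
    """Drop cells detecting fewer than ``min_genes_detected`` genes.

    A gene counts as detected in a cell when its value is at or above
    ``detection_threshold`` (default 1 expression unit, i.e. 1 FPKM on raw
    data). Cell order and the gene axis are preserved.
    """
    if E.space != "raw":
        raise ValidationError("filter_cells expects a raw-space matrix")
    detected = (E.values >= detection_threshold).sum(axis=1)
    keep = detected >= min_genes_detected
    if not keep.any():
        raise ValidationError(
            "all cells removed by filter; lower min_genes_detected or detection_threshold"
        )
    out = E.subset_cells(keep)
    logger.info("filter_cells: kept %d of %d cells (min_genes=%d, threshold=%g)",
                out.n_cells, E.n_cells, min_genes_detected, detection_threshold)
    return out


def log_transform(E: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); tags the result as log space."""
    if E.space != "raw":
        raise ValidationError("matrix is already log-transformed")
    return replace(E, values=np.log2(E.values + 1.0), space="log")
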