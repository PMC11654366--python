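"""UMI count matrices: I/O, gene filtering, and normalization transforms.

The container is deliberately small: a cells x genes integer count matrix
with cell/gene identifiers and an optional per-cell type label.  All
downstream stages (doublet mixing, decomposition, differential expression)
consume either raw counts or one of the normalized views produced here:

``cpm``
    counts-per-million scaling of each cell (row sums 1e6); the input
    representation fed to the decomposition networks.
``lognorm10k``
    per-cell scaling to a total of 10,000 followed by ln(x + 1); the
    starting point of the differential-expression preprocessing chain.
``residual``
    lognorm10k values with the per-cell total UMI count regressed out
    gene-by-gene (ordinary least squares with intercept).
``scaled``
    residuals z-scored per gene across cells (population standard
    deviation; zero-variance genes map to all zeros).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "ValidationError",
    "read_expression",
    "write_expression",
    "filter_genes",
    "cpm_normalize",
    "cpm_matrix",
    "lognorm_10k",
    "regress_out_totals",
    "scale_genes",
    "align_to_genes",
]

Provenance = Literal["cpm", "lognorm10k", "residual", "scaled"]


class ValidationError(ValueError):
    """Raised when a matrix violates the count-matrix invariants."""


def _check_unique(ids: Sequence[str], what: str) -> np.ndarray:
    arr = np.asarray(ids, dtype=object)
    if len(set(arr)) != len(arr):
        raise ValidationError(f"duplicate {what} ids")
    return arr


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix of non-negative integer UMI counts.

    Parameters
    ----------
    counts
        ``(n_cells, n_genes)`` array-like of non-negative integers.
    cell_ids, gene_ids
        Unique string identifiers; lengths must match the matrix shape.
    cell_type
        Optional per-cell label (e.g. ``"A"`` / ``"B"``).
    """

    counts: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be 2-dimensional")
        if np.issubdtype(counts.dtype, np.floating):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts contain non-integral entries")
            counts = np.round(counts).astype(np.int64)
        elif not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError(f"counts dtype {counts.dtype} is not numeric")
        if counts.size and counts.min() < 0:
            raise ValidationError("counts contain negative entries")
        self.counts = counts.astype(np.int64, copy=False)
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if len(self.cell_ids) != counts.shape[0]:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {counts.shape[0]} rows"
            )
        if len(self.gene_ids) != counts.shape[1]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {counts.shape[1]} columns"
            )
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
            if len(self.cell_type) != counts.shape[0]:
                raise ValidationError("cell_type length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> np.ndarray:
        """Per-cell total UMI counts."""
        return self.counts.sum(axis=1)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted (and reordered) to ``genes``."""
        index = pd.Index(self.gene_ids)
        locs = index.get_indexer(list(genes))
        if (locs < 0).any():
            missing = [g for g, l in zip(genes, locs) if l < 0]
            raise KeyError(f"genes not present: {missing[:5]}")
        return ExpressionMatrix(
            counts=self.counts[:, locs],
            cell_ids=self.cell_ids,
            gene_ids=np.asarray(list(genes), dtype=object),
            cell_type=self.cell_type,
        )

    def subset_cells(self, mask_or_idx) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_idx)
        return ExpressionMatrix(
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            cell_type=None if self.cell_type is None else self.cell_type[idx],
        )


@dataclass
class NormalizedMatrix:
    """Real-valued cells x genes matrix with a recorded transform provenance."""

    values: np.ndarray
    provenance: Provenance
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    parent: ExpressionMatrix | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.provenance == "cpm":
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1e6, rtol=1e-6):
                raise ValidationError("cpm rows must sum to 1e6")
        elif self.provenance == "lognorm10k":
            if self.values.size and self.values.min() < 0:
                raise ValidationError("lognorm10k values must be non-negative")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _mtx_companions(path: str) -> tuple[str, str]:
    base = os.path.splitext(path)[0]
    genes = base + ".genes.txt"
    cells = base + ".barcodes.txt"
    return genes, cells


def read_expression(
    path: str,
    format: Literal["mtx", "dense_delim"] = "dense_delim",
    *,
    genes_are_rows: bool = True,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a UMI count matrix.

    ``mtx`` expects a Matrix Market coordinate file alongside
    ``<stem>.genes.txt`` and ``<stem>.barcodes.txt`` one-column companion
    files; ``genes_are_rows`` declares the on-disk orientation.
    ``dense_delim`` expects a delimited table with a header row of gene ids
    and a first column of cell ids (tab by default, comma for ``.csv``).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "mtx":
        genes_path, cells_path = _mtx_companions(path)
        for companion in (genes_path, cells_path):
            if not os.path.exists(companion):
                raise FileNotFoundError(f"missing companion file: {companion}")
        mat = scipy.io.mmread(path)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        gene_ids = pd.read_csv(genes_path, header=None)[0].astype(str).to_numpy()
        cell_ids = pd.read_csv(cells_path, header=None)[0].astype(str).to_numpy()
        if genes_are_rows:
            dense = dense.T
        return ExpressionMatrix(dense, cell_ids=cell_ids, gene_ids=gene_ids)
    if format == "dense_delim":
        if sep is None:
            sep = "," if path.endswith(".csv") else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(
            df.to_numpy(),
            cell_ids=df.index.astype(str).to_numpy(),
            gene_ids=df.columns.astype(str).to_numpy(),
        )
    raise ValueError(f"unknown format: {format!r}")


def write_expression(
    matrix: ExpressionMatrix,
    path: str,
    format: Literal["mtx", "dense_delim"] = "dense_delim",
    *,
    genes_are_rows: bool = True,
    sep: str | None = None,
) -> None:
    """Write a count matrix in one of the two supported text formats."""
    if format == "mtx":
        genes_path, cells_path = _mtx_companions(path)
        dense = matrix.counts.T if genes_are_rows else matrix.counts
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(dense))
        pd.Series(matrix.gene_ids).to_csv(genes_path, index=False, header=False)
        pd.Series(matrix.cell_ids).to_csv(cells_path, index=False, header=False)
        return
    if format == "dense_delim":
        if sep is None:
            sep = "," if path.endswith(".csv") else "\t"
        df = pd.DataFrame(
            matrix.counts, index=matrix.cell_ids, columns=matrix.gene_ids
        )
        df.to_csv(path, sep=sep)
        return
    raise ValueError(f"unknown format: {format!r}")


# ---------------------------------------------------------------------------
# Gene filtering
# ---------------------------------------------------------------------------

def filter_genes(
    matrices_by_type: Sequence[ExpressionMatrix],
    min_umi: int = 1,
    min_cell_frac: float = 0.04,
    *,
    mode: Literal["all", "any"] = "all",
) -> list[str]:
    """Select genes expressed in a minimum fraction of cells per cell type.

    A gene passes in a cell type when the fraction of that type's cells
    with at least ``min_umi`` counts is >= ``min_cell_frac``.  With
    ``mode="all"`` (default) a gene must pass in every provided type; with
    ``mode="any"`` in at least one.  Only genes present in all matrices are
    considered, and the output follows the first matrix's gene order.
    """
    if len(matrices_by_type) == 0:
        raise ValueError("at least one expression matrix is required")
    shared = set(matrices_by_type[0].gene_ids)
    for m in matrices_by_type[1:]:
        shared &= set(m.gene_ids)
    universe = [g for g in matrices_by_type[0].gene_ids if g in shared]

    passing = []
    for m in matrices_by_type:
        sub = m.subset_genes(universe)
        frac = (sub.counts >= min_umi).mean(axis=0)
        passing.append(frac >= min_cell_frac)
    stacked = np.vstack(passing)
    keep = stacked.all(axis=0) if mode == "all" else stacked.any(axis=0)
    return [g for g, k in zip(universe, keep) if k]


# ---------------------------------------------------------------------------
# Normalization transforms
# ---------------------------------------------------------------------------

def cpm_normalize(counts: np.ndarray) -> np.ndarray:
    """Scale one cell's count vector to counts-per-million (sum 1e6)."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot CPM-normalize an all-zero count vector")
    if counts.min() < 0:
        raise ValueError("negative counts")
    return counts / total * 1e6


def cpm_matrix(values: np.ndarray, dtype=np.float64) -> np.ndarray:
    """Row-wise CPM scaling of a cells x genes matrix (real-valued input ok).

    Mixtures produced by the alpha-mixing equation are fractional, so this
    accepts any non-negative real matrix with positive row sums.
    """
    values = np.asarray(values, dtype=np.float64)
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = int(np.where(totals <= 0)[0][0])
        raise ValueError(f"row {bad} has non-positive total; cannot CPM-normalize")
    return (values / totals[:, None] * 1e6).astype(dtype)


def lognorm_10k(matrix: ExpressionMatrix) -> NormalizedMatrix:
    """Scale each cell to a total of 10,000 and apply ln(x + 1)."""
    totals = matrix.totals()
    if (totals == 0).any():
        bad = matrix.cell_ids[np.where(totals == 0)[0][0]]
        raise ValueError(f"cell {bad!r} has zero total count")
    norm = matrix.counts / totals[:, None] * 1e4
    return NormalizedMatrix(
        np.log1p(norm),
        provenance="lognorm10k",
        cell_ids=matrix.cell_ids,
        gene_ids=matrix.gene_ids,
        parent=matrix,
    )


def regress_out_totals(
    matrix: NormalizedMatrix, totals: np.ndarray
) -> NormalizedMatrix:
    """Remove the linear effect of per-cell total UMI counts, per gene.

    For each gene, expression is regressed on the totals by ordinary least
    squares with an intercept, and the residuals are returned.
    """
    totals = np.asarray(totals, dtype=np.float64)
    n = matrix.values.shape[0]
    if totals.shape != (n,):
        raise ValueError(f"expected {n} totals, got shape {totals.shape}")
    if n < 2:
        raise ValueError("regression requires at least 2 cells")
    design = np.column_stack([np.ones(n), totals])
    # one lstsq solve covers every gene: coef is (2, n_genes)
    coef, *_ = np.linalg.lstsq(design, matrix.values, rcond=None)
    residuals = matrix.values - design @ coef
    return NormalizedMatrix(
        residuals,
        provenance="residual",
        cell_ids=matrix.cell_ids,
        gene_ids=matrix.gene_ids,
        parent=matrix.parent,
    )


def scale_genes(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Z-score each gene across cells (population standard deviation).

    Zero-variance genes become all zeros instead of raising: they carry no
    information for rank or location tests downstream.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("scaling requires at least 2 cells")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0)  # population (1/n) sd
    centered = matrix.values - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    return NormalizedMatrix(
        scaled,
        provenance="scaled",
        cell_ids=matrix.cell_ids,
        gene_ids=matrix.gene_ids,
        parent=matrix.parent,
    )


def align_values_to_genes(
    values: np.ndarray,
    gene_ids: Sequence[str],
    genes: Sequence[str],
    *,
    min_overlap: float = 0.5,
) -> np.ndarray:
    """Reorder the columns of ``values`` to ``genes``, zero-filling absences.

    Raises if fewer than ``min_overlap`` of the requested genes are present
    (a guard against wrong-species or wrong-panel inputs).
    """
    values = np.asarray(values, dtype=np.float64)
    index = pd.Index(gene_ids)
    locs = index.get_indexer(list(genes))
    present = locs >= 0
    if present.mean() < min_overlap:
        raise ValueError(
            f"only {present.sum()}/{len(genes)} model genes present in input "
            f"(need >= {min_overlap:.0%})"
        )
    out = np.zeros((values.shape[0], len(genes)), dtype=np.float64)
    out[:, present] = values[:, locs[present]]
    return out


def align_to_genes(
    matrix: ExpressionMatrix, genes: Sequence[str], *, min_overlap: float = 0.5
) -> np.ndarray:
    """Return ``matrix`` counts reordered to ``genes``, zero-filling absences."""
    return align_values_to_genes(
        matrix.counts, matrix.gene_ids, genes, min_overlap=min_overlap
    )
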