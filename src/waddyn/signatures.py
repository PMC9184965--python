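"""Correlation signatures of transitions and attractors in expression data.

For a cells × genes expression matrix, two complementary Pearson statistics
distinguish a population in transit between attractors from one settled in an
attractor: during a transition, cells spread along a curve in gene space, so
gene–gene correlations are strong (collinear change) while cell–cell
correlations between raw expression vectors are comparatively low; inside an
attractor the cloud is roughly isotropic and the pattern reverses.  The
module reports both statistics per cell group without thresholding.

Undefined correlations (zero-variance genes or constant cell vectors) are
flagged and excluded from averages, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "gene_gene_corr",
    "cell_cell_corr",
    "transition_report",
    "standardize_genes",
    "NoDefinedPairsError",
]


class NoDefinedPairsError(ValueError):
    """No gene or cell pair has a defined Pearson correlation."""


@dataclass
class ExpressionMatrix:
    """Cells × genes expression values with row and column identifiers."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-d cells x genes matrix")
        n_c, n_g = self.values.shape
        if n_c != len(self.cell_ids) or n_g != len(self.gene_ids):
            raise ValueError("id lists must match the matrix shape")
        if len(set(self.cell_ids)) != n_c:
            raise ValueError("cell ids must be unique")
        if len(set(self.gene_ids)) != n_g:
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, cell_names) -> "ExpressionMatrix":
        ix = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_names if str(c) not in ix]
        if missing:
            raise KeyError(f"unknown cells: {missing}")
        rows = [ix[str(c)] for c in cell_names]
        return ExpressionMatrix(
            self.values[rows], [self.cell_ids[r] for r in rows], list(self.gene_ids)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="cell")

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "ExpressionMatrix":
        """Read a header row of gene ids and a first column of cell ids.

        ``sep=None`` infers comma vs tab from the file name (``.tsv``/``.tab``
        read as tab-separated).
        """
        if sep is None:
            sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
        frame = pd.read_csv(path, sep=sep, index_col=0)
        return cls(
            frame.to_numpy(float), [str(i) for i in frame.index], [str(c) for c in frame.columns]
        )


def _require_min_shape(matrix: ExpressionMatrix) -> None:
    if matrix.n_cells < 2 or matrix.n_genes < 2:
        raise ValueError(
            "correlations need at least 2 cells and 2 genes, got "
            f"{matrix.n_cells} x {matrix.n_genes}"
        )


def standardize_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Optional pre-step: per-gene z-scores (zero-variance genes left at 0)."""
    v = matrix.values
    mu = v.mean(axis=0, keepdims=True)
    sd = v.std(axis=0, keepdims=True)
    z = np.where(sd > 0, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return ExpressionMatrix(z, list(matrix.cell_ids), list(matrix.gene_ids))


@dataclass
class GeneGeneResult:
    """Gene x gene Pearson matrix with undefined genes flagged."""

    matrix: pd.DataFrame  # NaN where undefined
    mean_abs_offdiag: float
    undefined_genes: list = field(default_factory=list)


def gene_gene_corr(matrix: ExpressionMatrix) -> GeneGeneResult:
    """Pearson correlation of every gene pair across cells.

    Genes with zero variance across cells have undefined correlations; their
    rows and columns are flagged and reported as NaN, and the summary is the
    mean of the absolute off-diagonal values over defined pairs only.  All
    genes constant raises :class:`NoDefinedPairsError`.
    """
    _require_min_shape(matrix)
    v = matrix.values
    sd = v.std(axis=0)
    defined = sd > 0
    undefined = [g for g, ok in zip(matrix.gene_ids, defined) if not ok]
    if defined.sum() < 2:
        raise NoDefinedPairsError(
            "no gene pair has a defined correlation (all or all-but-one genes constant)"
        )
    corr = np.full((matrix.n_genes, matrix.n_genes), np.nan)
    sub = np.corrcoef(v[:, defined], rowvar=False)
    ij = np.flatnonzero(defined)
    corr[np.ix_(ij, ij)] = sub
    off = sub[~np.eye(sub.shape[0], dtype=bool)]
    frame = pd.DataFrame(corr, index=matrix.gene_ids, columns=matrix.gene_ids)
    return GeneGeneResult(
        matrix=frame,
        mean_abs_offdiag=float(np.mean(np.abs(off))),
        undefined_genes=undefined,
    )


@dataclass
class CellCellResult:
    """Mean pairwise Pearson correlation between raw cell vectors."""

    mean_corr: float
    n_pairs: int
    excluded_cells: list = field(default_factory=list)


def cell_cell_corr(matrix: ExpressionMatrix) -> CellCellResult:
    """Pearson correlation between every unordered pair of cell vectors.

    The correlation is taken across genes between raw (uncentered-by-gene)
    expression vectors.  Cells whose vector is constant across genes have no
    defined correlation; they are flagged, excluded from the average and
    reported.  Fewer than two usable cells raises
    :class:`NoDefinedPairsError`.
    """
    _require_min_shape(matrix)
    v = matrix.values
    sd = v.std(axis=1)
    usable = sd > 0
    excluded = [c for c, ok in zip(matrix.cell_ids, usable) if not ok]
    if usable.sum() < 2:
        raise NoDefinedPairsError(
            "fewer than two cells have non-constant expression vectors"
        )
    sub = np.corrcoef(v[usable], rowvar=True)
    iu = np.triu_indices_from(sub, k=1)
    return CellCellResult(
        mean_corr=float(np.mean(sub[iu])),
        n_pairs=int(iu[0].size),
        excluded_cells=excluded,
    )


def transition_report(matrix: ExpressionMatrix, cell_groups: dict) -> pd.DataFrame:
    """Both correlation summaries per named group of cells.

    ``cell_groups`` maps a group label to the cell ids it contains; the
    groups must partition the matrix's cells.  Groups with fewer than two
    cells are skipped with a notice column rather than an error.  No
    thresholding is applied: a transition-like group shows high mean
    ``|gene-gene|`` with low cell–cell correlation, an attractor-like group
    the reverse, and the report simply states both numbers.
    """
    all_cells = [str(c) for g in cell_groups.values() for c in g]
    if sorted(all_cells) != sorted(matrix.cell_ids):
        raise ValueError("cell_groups must partition the matrix's cells exactly")
    rows = []
    for label, cells in cell_groups.items():
        row = {"group": label, "n_cells": len(cells)}
        if len(cells) < 2:
            row.update(
                mean_abs_gene_gene=np.nan,
                mean_cell_cell=np.nan,
                notice="skipped: fewer than 2 cells",
            )
        else:
            sub = matrix.subset(cells)
            notices = []
            try:
                gg = gene_gene_corr(sub)
                row["mean_abs_gene_gene"] = gg.mean_abs_offdiag
                if gg.undefined_genes:
                    notices.append(f"undefined genes: {gg.undefined_genes}")
            except NoDefinedPairsError as err:
                row["mean_abs_gene_gene"] = np.nan
                notices.append(str(err))
            try:
                cc = cell_cell_corr(sub)
                row["mean_cell_cell"] = cc.mean_corr
                if cc.excluded_cells:
                    notices.append(f"excluded cells: {cc.excluded_cells}")
            except NoDefinedPairsError as err:
                row["mean_cell_cell"] = np.nan
                notices.append(str(err))
            row["notice"] = "; ".join(notices)
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["group", "n_cells", "mean_abs_gene_gene", "mean_cell_cell", "notice"]
    )
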