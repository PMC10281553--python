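"""Shared in-memory containers.

The central object is :class:`ExpressionMatrix`: a dense cells x genes
matrix of nonnegative expression values with unique cell and gene labels
and an optional per-cell pseudotime.  It is deliberately lightweight — a
thin, validated wrapper around a numpy array — so that every module can
exchange data without imposing a heavier ecosystem container on users.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ShapeError, DomainError


@dataclass
class ExpressionMatrix:
    """Cells x genes expression matrix.

    Parameters
    ----------
    values
        ``(n_cells, n_genes)`` array of nonnegative expression values.
    cell_ids
        Unique cell identifiers, one per row.
    gene_names
        Unique gene names, one per column.
    pseudotime
        Optional per-cell pseudotime (rank or continuous value).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_names: list[str]
    pseudotime: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("expression values must be a 2-D cells x genes array")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_names = [str(g) for g in self.gene_names]
        n_c, n_g = self.values.shape
        if len(self.cell_ids) != n_c:
            raise ShapeError(
                f"{len(self.cell_ids)} cell ids for {n_c} matrix rows"
            )
        if len(self.gene_names) != n_g:
            raise ShapeError(
                f"{len(self.gene_names)} gene names for {n_g} matrix columns"
            )
        if len(set(self.cell_ids)) != n_c:
            raise DomainError("cell ids are not unique")
        if len(set(self.gene_names)) != n_g:
            raise DomainError("gene names are not unique")
        if np.any(self.values < 0):
            raise DomainError("expression values must be nonnegative")
        if self.pseudotime is not None:
            self.pseudotime = np.asarray(self.pseudotime, dtype=float)
            if self.pseudotime.shape != (n_c,):
                raise ShapeError(
                    f"pseudotime length {self.pseudotime.shape} does not match "
                    f"{n_c} cells"
                )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, names) -> np.ndarray:
        """Column indices of ``names``; raises if any gene is absent."""
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in names if g not in lookup]
        if missing:
            raise DomainError(f"genes not in matrix: {missing[:10]}")
        return np.array([lookup[g] for g in names], dtype=int)

    def subset_cells(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_names=list(self.gene_names),
            pseudotime=None if self.pseudotime is None else self.pseudotime[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_names)
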