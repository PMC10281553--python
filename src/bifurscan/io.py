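"""Readers and writers for the plain-text formats the tool touches.

Matrices travel either as dense TSV (cells x genes, header = gene
names, first column = cell id) or as a MatrixMarket coordinate triple
(``matrix.mtx`` + one-gene-per-line ``genes.tsv`` + ``cells.tsv``).
Pseudotime is a two-column TSV (cell id, value); gene sets use the GMT
dialect (tab-separated: set name, description, gene symbols).
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix
from .errors import DomainError, FormatError

logger = logging.getLogger("bifurscan")

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_pseudotime",
    "read_gene_sets",
    "read_gene_list",
    "write_scan_tsv",
    "write_report_json",
]

_FLOAT_FMT = "%.10g"


def _read_labels(path) -> list[str]:
    """One label per line (first tab-separated field)."""
    labels = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                labels.append(line.split("\t")[0])
    return labels


def read_matrix(
    path,
    fmt: str = "auto",
    genes_path=None,
    cells_path=None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from dense TSV or MatrixMarket.

    ``fmt="auto"`` decides by extension (``.mtx`` vs anything else).
    For MatrixMarket, ``genes_path`` and ``cells_path`` are required;
    the stored orientation is assumed cells x genes unless
    ``transpose=True``.  A warning is logged when the label files only
    match the transposed orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt == "auto":
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "mtx":
        if genes_path is None or cells_path is None:
            raise DomainError("MatrixMarket input needs genes_path and cells_path")
        try:
            M = scipy.io.mmread(path)
        except Exception as exc:
            raise FormatError(f"malformed MatrixMarket file {path}: {exc}") from None
        V = np.asarray(M.todense() if scipy.sparse.issparse(M) else M, dtype=float)
        genes = _read_labels(genes_path)
        cells = _read_labels(cells_path)
        if transpose:
            V = V.T
        if V.shape != (len(cells), len(genes)):
            if V.T.shape == (len(cells), len(genes)):
                logger.warning(
                    "matrix %s matches labels only when transposed; transposing",
                    path,
                )
                V = V.T
            else:
                raise FormatError(
                    f"matrix shape {V.shape} does not match {len(cells)} cells "
                    f"x {len(genes)} genes"
                )
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        seen: set[str] = set()
        dupes = [g for g in header if g in seen or seen.add(g)]
        if dupes:
            raise FormatError(f"duplicate gene names in {path}: {dupes[:10]}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = header  # undo any pandas dedup mangling
        if df.index.duplicated().any():
            raise FormatError(f"duplicate cell ids in {path}")
        if transpose:
            df = df.T
        V = df.to_numpy(dtype=float)
        genes = [str(c) for c in df.columns]
        cells = [str(i) for i in df.index]
    n_zero_rows = int(np.sum(V.sum(axis=1) == 0))
    n_zero_cols = int(np.sum(V.sum(axis=0) == 0))
    if n_zero_rows or n_zero_cols:
        logger.info(
            "matrix %s: %d all-zero cells, %d all-zero genes",
            path, n_zero_rows, n_zero_cols,
        )
    return ExpressionMatrix(values=V, cell_ids=cells, gene_names=genes)


def write_matrix(G: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    """Write a matrix as dense TSV or as a MatrixMarket triple.

    For ``fmt="mtx"``, ``path`` is the ``.mtx`` file; ``genes.tsv`` and
    ``cells.tsv`` are written next to it.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        df = G.to_dataframe()
        df.index.name = "cell_id"
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    elif fmt == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(G.values))
        path.with_name("genes.tsv").write_text("\n".join(G.gene_names) + "\n")
        path.with_name("cells.tsv").write_text("\n".join(G.cell_ids) + "\n")
    else:
        raise DomainError(f"unknown matrix format {fmt!r}")


def read_pseudotime(path, cell_ids: list[str]) -> np.ndarray:
    """Read a cell id -> pseudotime TSV, aligned to ``cell_ids``.

    The file has two tab-separated columns (cell id, value); a header
    line is allowed.  Every matrix cell must be present; missing cells
    and non-numeric values are reported with their identity/line.
    """
    mapping: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            cid, raw = parts[0], parts[1]
            try:
                value = float(raw)
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise FormatError(
                    f"{path}:{lineno}: non-numeric pseudotime {raw!r}"
                ) from None
            mapping[cid] = value
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        raise DomainError(
            f"pseudotime missing for {len(missing)} cells: {missing[:10]}"
        )
    return np.array([mapping[c] for c in cell_ids], dtype=float)


def read_gene_sets(path) -> dict[str, list[str]]:
    """Parse a GMT file: set name, description, then gene symbols."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need name, description and "
                    "at least one gene"
                )
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def read_gene_list(path) -> list[str]:
    """One gene symbol per line."""
    genes = [line.strip() for line in open(path) if line.strip()]
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    return genes


def write_scan_tsv(traj, path) -> None:
    """Write the per-bin scan table at fixed float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_report_json(report, path, extra: dict | None = None) -> None:
    """Write a transition report (plus optional metadata) as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    if extra:
        payload = {**payload, **extra}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
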