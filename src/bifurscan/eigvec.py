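"""Eigenvector-centric analytics of bifurcation directions.

At a bifurcation the principal covariance eigenvector equals (up to a
sign) the slow eigenvector of the underlying Jacobian, so its loadings
identify the genes along which stability is lost.  This module tracks
the principal eigenvector across pseudotime bins, correlates it between
bins to reveal epochs with a shared direction, projects cells onto
candidate directions, scores gene-set (pathway) loadings, tests
projection distributions for bimodality, and splits coexisting
transcriptomic modes with a two-component Gaussian mixture whose labels
can be propagated to the whole trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .containers import ExpressionMatrix
from .ctl_core import covariance_eig
from .errors import (
    DegenerateInputError,
    DomainError,
    ShapeError,
    UndefinedStatisticError,
)
from .trajectory import BinnedTrajectory

__all__ = [
    "EigvecSeries",
    "GeneSetWeights",
    "MixtureSplit",
    "principal_eigvec_series",
    "eigenvector_correlation_map",
    "project",
    "projection_distribution",
    "variance_fraction",
    "category_weights",
    "fit_mixture_split",
    "propagate_labels",
    "is_bimodal",
]


@dataclass
class EigvecSeries:
    """Principal covariance eigenvector of every pseudotime bin."""

    loadings: np.ndarray  # (n_bins, n_genes), unit rows, sign-fixed
    bin_labels: np.ndarray
    gene_names: list[str] | None = None


@dataclass
class GeneSetWeights:
    """Average eigenvector loading magnitude per gene-set category."""

    table: pd.DataFrame  # columns: category, W, n_genes; sorted by W desc
    unmatched: dict[str, int]  # per category: genes absent from the matrix


@dataclass
class MixtureSplit:
    """Fitted two-component Gaussian mixture over a bin's cells."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    labels: np.ndarray  # per-cell "a"/"b"
    separation: float
    seed: int
    model: GaussianMixture
    basis: np.ndarray | None  # (d, n_genes) projection basis, None = full
    center: np.ndarray | None
    gene_names: list[str] | None = None


def principal_eigvec_series(G, bins: BinnedTrajectory) -> EigvecSeries:
    """Compute the per-bin principal covariance eigenvector."""
    if isinstance(G, ExpressionMatrix):
        V, names = G.values, G.gene_names
    else:
        V, names = np.asarray(G, dtype=float), None
    rows = [covariance_eig(V[idx], k=1).s1 for idx in bins.bins]
    return EigvecSeries(
        loadings=np.vstack(rows), bin_labels=bins.labels, gene_names=names
    )


def eigenvector_correlation_map(
    series: EigvecSeries, absolute: bool = False
) -> np.ndarray:
    """Pairwise Pearson correlation of eigenvector loading profiles.

    With ``absolute=True`` correlations are computed on absolute
    loadings (sign-free comparison).
    """
    L = series.loadings
    if L.ndim != 2 or L.shape[0] < 2:
        raise DomainError("need at least 2 bins of eigenvectors")
    if absolute:
        L = np.abs(L)
    R = np.corrcoef(L)
    np.fill_diagonal(R, 1.0)
    return R


def _unit(vector: np.ndarray) -> np.ndarray:
    v = np.asarray(vector, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise DomainError("cannot project onto a zero vector")
    return v / n


def project(G, vector: np.ndarray, center: bool = False) -> np.ndarray:
    """Per-cell scalar coordinate along a (unit-normalized) direction."""
    V = G.values if isinstance(G, ExpressionMatrix) else np.asarray(G, dtype=float)
    v = _unit(vector)
    if V.shape[1] != v.size:
        raise ShapeError(
            f"vector length {v.size} does not match {V.shape[1]} genes"
        )
    if center:
        V = V - V.mean(axis=0)
    return V @ v


def is_bimodal(x: np.ndarray, delta_bic: float = 10.0, seed: int = 0) -> tuple[bool, float]:
    """Whether a 1-D sample prefers two Gaussian components over one.

    Returns ``(flag, bic1 - bic2)``; the flag is set when the BIC
    improvement of the two-component fit exceeds ``delta_bic``.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1)
    if x.size < 4 or np.std(x) == 0:
        return False, 0.0
    g1 = GaussianMixture(1, random_state=seed).fit(x)
    g2 = GaussianMixture(2, n_init=3, random_state=seed).fit(x)
    delta = g1.bic(x) - g2.bic(x)
    return bool(delta > delta_bic), float(delta)


def projection_distribution(
    G,
    bins: BinnedTrajectory,
    vector: np.ndarray,
    delta_bic: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin summary of cell projections along a direction.

    Returns a frame with per-bin mean, standard deviation and a
    bimodality flag from a 1-vs-2 component Gaussian mixture comparison.
    """
    V = G.values if isinstance(G, ExpressionMatrix) else np.asarray(G, dtype=float)
    v = _unit(vector)
    rows = []
    for label, idx in zip(bins.labels, bins.bins):
        if len(idx) == 0:
            raise DomainError(f"bin {label} is empty")
        p = V[idx] @ v
        flag, delta = is_bimodal(p, delta_bic=delta_bic, seed=seed)
        rows.append(
            {
                "bin": int(label),
                "n_cells": len(idx),
                "mean": p.mean(),
                "sd": p.std(ddof=1) if len(idx) > 1 else 0.0,
                "bimodal": flag,
                "delta_bic": delta,
            }
        )
    return pd.DataFrame(rows)


def variance_fraction(G_bin, vector: np.ndarray) -> float:
    """Fraction of total variance captured along a unit direction.

    The variance of centred projections divided by the total variance
    (sum of per-gene variances); equals omega_1 / sum(omega_i) when the
    direction is the principal eigenvector.
    """
    V = G_bin.values if isinstance(G_bin, ExpressionMatrix) else np.asarray(G_bin, dtype=float)
    v = _unit(vector)
    if V.shape[0] < 2:
        raise UndefinedStatisticError("variance needs at least 2 cells")
    total = V.var(axis=0, ddof=1).sum()
    if total == 0:
        raise UndefinedStatisticError("matrix has zero total variance")
    along = np.var((V - V.mean(axis=0)) @ v, ddof=1)
    return float(along / total)


def category_weights(
    vector: np.ndarray,
    gene_sets: dict[str, list[str]],
    gene_names: list[str],
    min_size: int = 1,
    signed: bool = False,
) -> GeneSetWeights:
    """Average loading weight of each gene-set category.

    ``W_c`` is the mean over matched genes of the absolute eigenvector
    loading (``signed=True`` averages raw loadings instead).  Genes
    absent from the matrix are ignored but counted; categories with
    fewer than ``min_size`` matched genes are dropped.
    """
    if not gene_sets:
        raise DomainError("gene_sets is empty")
    if min_size < 1:
        raise DomainError("min_size must be >= 1")
    v = np.asarray(vector, dtype=float)
    if v.size != len(gene_names):
        raise ShapeError("vector length does not match gene_names")
    lookup = {g: i for i, g in enumerate(gene_names)}
    rows, unmatched = [], {}
    for cat, genes in gene_sets.items():
        idx = [lookup[g] for g in genes if g in lookup]
        unmatched[cat] = len(genes) - len(idx)
        if len(idx) < min_size:
            continue
        w = v[idx] if signed else np.abs(v[idx])
        rows.append({"category": cat, "W": float(w.mean()), "n_genes": len(idx)})
    if not rows:
        raise DomainError(f"no category has >= {min_size} genes in the matrix")
    table = (
        pd.DataFrame(rows)
        .sort_values("W", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return GeneSetWeights(table=table, unmatched=unmatched)


def fit_mixture_split(
    G_bin,
    vector: np.ndarray | None = None,
    seed: int = 0,
    n_pcs: int = 10,
    mode: str = "pca",
) -> MixtureSplit:
    """Fit a two-component Gaussian mixture to a bin's cells.

    By default cells are first projected onto the bin's top ``n_pcs``
    principal axes and the mixture uses diagonal covariances there,
    which avoids singular full-dimensional covariance estimates.  Pass
    ``vector`` to fit on a single given direction, or ``mode="full"``
    to fit diagonal covariances in full gene space.  Component "a" is
    the one whose mean has the smaller first coordinate, making labels
    deterministic given the seed.
    """
    V = G_bin.values if isinstance(G_bin, ExpressionMatrix) else np.asarray(G_bin, dtype=float)
    names = G_bin.gene_names if isinstance(G_bin, ExpressionMatrix) else None
    if V.shape[0] < 20:
        raise DomainError("need at least 20 cells to fit a mixture")
    if V.std(axis=0).sum() == 0:
        raise DegenerateInputError("bin has zero variance; mixture fit is degenerate")
    center = V.mean(axis=0)
    if vector is not None:
        basis = _unit(vector).reshape(1, -1)
    elif mode == "pca":
        k = int(min(n_pcs, V.shape[0] - 1, V.shape[1]))
        basis = covariance_eig(V, k=k).eigenvectors
    elif mode == "full":
        basis = None
    else:
        raise DomainError(f"unknown mixture mode {mode!r}")
    Y = (V - center) @ basis.T if basis is not None else V - center
    gm = GaussianMixture(
        n_components=2, covariance_type="diag", n_init=5, random_state=seed
    ).fit(Y)
    order = np.argsort(gm.means_[:, 0])
    raw = gm.predict(Y)
    labels = np.where(raw == order[0], "a", "b")
    d = gm.means_[order[1]] - gm.means_[order[0]]
    pooled = 0.5 * (gm.covariances_[0] + gm.covariances_[1])
    separation = float(np.sqrt(np.sum(d**2 / np.maximum(pooled, 1e-300))))
    return MixtureSplit(
        means=gm.means_[order],
        variances=gm.covariances_[order],
        weights=gm.weights_[order],
        labels=labels,
        separation=separation,
        seed=seed,
        model=gm,
        basis=basis,
        center=center,
        gene_names=names,
    )


def propagate_labels(
    split: MixtureSplit, G, bins: BinnedTrajectory
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Assign every cell of the trajectory to a mixture component.

    Cells are mapped into the split's fitted space and labelled by the
    mixture's posterior.  Returns a per-bin composition frame (fraction
    of cells in each cluster) and per-cluster omega_1 trajectories
    (NaN where a cluster has fewer than 2 cells in a bin).
    """
    if isinstance(G, ExpressionMatrix):
        if split.gene_names is not None and G.gene_names != split.gene_names:
            raise DomainError("gene names do not match the fitted mixture")
        V = G.values
    else:
        V = np.asarray(G, dtype=float)
    if V.shape[1] != split.center.size:
        raise ShapeError("gene dimension does not match the fitted mixture")
    Y = (V - split.center) @ split.basis.T if split.basis is not None else V - split.center
    raw = split.model.predict(Y)
    order = np.argsort(split.model.means_[:, 0])
    all_labels = np.where(raw == order[0], "a", "b")
    rows, omega = [], {"a": np.full(bins.n_bins, np.nan), "b": np.full(bins.n_bins, np.nan)}
    for i, (label, idx) in enumerate(zip(bins.labels, bins.bins)):
        lab = all_labels[idx]
        frac_a = float(np.mean(lab == "a"))
        rows.append(
            {
                "bin": int(label),
                "n_cells": len(idx),
                "frac_a": frac_a,
                "frac_b": 1.0 - frac_a,
            }
        )
        for name in ("a", "b"):
            sub = np.asarray(idx)[lab == name]
            if sub.size >= 2:
                omega[name][i] = covariance_eig(V[sub], k=1).omega1
    return pd.DataFrame(rows), omega
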