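"""Linear stability and stationary covariance machinery.

Near a stable fixed point, expression fluctuations behave as a
multivariate Ornstein-Uhlenbeck process whose stationary covariance C
solves the continuous-time Lyapunov equation

.. math::  J C + C J^T + Q = 0,

with J the Jacobian of the dynamics and Q the (diagonal) noise
covariance.  As the largest Jacobian eigenvalue approaches zero the
covariance diverges along the corresponding eigenvector, so the
principal covariance eigenpair (omega_1, s_1) — computed here from the
reduced SVD of the centred expression matrix — carries the location and
direction of an impending bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_continuous_lyapunov
from sklearn.utils.extmath import randomized_svd

from .containers import ExpressionMatrix
from .errors import DomainError, ShapeError, StabilityError, UndefinedStatisticError
from .grn_sim import GRNParams

__all__ = [
    "LyapunovSolution",
    "CovarianceSummary",
    "solve_lyapunov",
    "covariance_eig",
    "pearson_matrix",
    "PearsonResult",
    "eigvec_alignment",
    "driver_responder_correlations",
]

# above this size, use randomized SVD instead of a full decomposition
_FULL_SVD_LIMIT = 2000


@dataclass
class LyapunovSolution:
    """Stationary covariance of a linear OU process."""

    C: np.ndarray
    residual: float  # relative norm of J C + C J^T + Q

    @property
    def principal(self) -> tuple[float, np.ndarray]:
        """Largest eigenvalue of C and its sign-fixed unit eigenvector."""
        vals, vecs = np.linalg.eigh(self.C)
        v = vecs[:, -1]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        return float(vals[-1]), v


@dataclass
class CovarianceSummary:
    """Eigendecomposition of a sample gene-gene covariance matrix.

    Eigenvalues are sorted descending; eigenvectors are unit norm with
    the deterministic sign convention that the largest-magnitude
    loading is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (k, n_genes)
    n_cells: int
    gene_names: list[str] | None = None
    correlations: np.ndarray | None = None

    @property
    def omega1(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def s1(self) -> np.ndarray:
        return self.eigenvectors[0]


def solve_lyapunov(J: np.ndarray, Q: np.ndarray) -> LyapunovSolution:
    """Solve the continuous-time Lyapunov equation J C + C J^T + Q = 0.

    ``J`` must be Hurwitz (all eigenvalues with negative real part) and
    ``Q`` symmetric positive semidefinite of matching dimension; the
    returned covariance is then symmetric PSD.  Uses the
    Bartels-Stewart algorithm.
    """
    J = np.asarray(J, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ShapeError(f"J must be square, got shape {J.shape}")
    if Q.shape != J.shape:
        raise ShapeError(f"Q shape {Q.shape} does not match J shape {J.shape}")
    if not np.allclose(Q, Q.T, atol=1e-10):
        raise DomainError("Q must be symmetric")
    eigs = np.linalg.eigvals(J)
    if np.max(eigs.real) >= 0:
        raise StabilityError(
            f"J is not Hurwitz (max Re(eig) = {np.max(eigs.real):.3g})"
        )
    C = solve_continuous_lyapunov(J, -Q)
    C = 0.5 * (C + C.T)
    scale = max(np.linalg.norm(Q), np.linalg.norm(J @ C, "fro"), 1e-300)
    residual = float(np.linalg.norm(J @ C + C @ J.T + Q, "fro") / scale)
    return LyapunovSolution(C=C, residual=residual)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip rows so the largest-magnitude component of each is positive."""
    idx = np.argmax(np.abs(vecs), axis=1)
    signs = np.sign(vecs[np.arange(vecs.shape[0]), idx])
    signs[signs == 0] = 1.0
    return vecs * signs[:, None]


def covariance_eig(
    X, k: int = 1, gene_names: list[str] | None = None, seed: int = 0
) -> CovarianceSummary:
    """Top-k eigenpairs of the sample covariance via reduced SVD.

    The matrix is column-centred and its singular values sigma_i are
    converted to covariance eigenvalues ``omega_i = sigma_i^2 /
    (n_cells - 1)`` (unbiased divisor).  For matrices whose smaller
    dimension exceeds a few thousand, a seeded randomized SVD is used.
    """
    if isinstance(X, ExpressionMatrix):
        gene_names = gene_names or X.gene_names
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError("expected a 2-D cells x genes matrix")
    n_c, n_g = X.shape
    if n_c < 2:
        raise UndefinedStatisticError(
            "covariance is undefined for fewer than 2 cells"
        )
    k = int(min(k, n_c, n_g))
    Xc = X - X.mean(axis=0)
    if min(n_c, n_g) <= _FULL_SVD_LIMIT:
        _, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        sv, Vt = sv[:k], Vt[:k]
    else:
        _, sv, Vt = randomized_svd(Xc, n_components=k, random_state=seed)
    omega = sv**2 / (n_c - 1)
    return CovarianceSummary(
        eigenvalues=omega,
        eigenvectors=_fix_signs(Vt),
        n_cells=n_c,
        gene_names=gene_names,
    )


@dataclass
class PearsonResult:
    """Pairwise Pearson correlations with zero-variance bookkeeping."""

    R: np.ndarray  # NaN where undefined
    zero_variance: np.ndarray  # boolean mask over genes
    gene_names: list[str] | None = None

    @property
    def offdiag_values(self) -> np.ndarray:
        """Defined off-diagonal correlations (each unordered pair once)."""
        iu = np.triu_indices_from(self.R, k=1)
        vals = self.R[iu]
        return vals[np.isfinite(vals)]


def pearson_matrix(X, gene_names: list[str] | None = None) -> PearsonResult:
    """Gene-gene Pearson correlation matrix.

    Zero-variance genes yield NaN rows/columns and are excluded from
    the off-diagonal value distribution.
    """
    if isinstance(X, ExpressionMatrix):
        gene_names = gene_names or X.gene_names
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise UndefinedStatisticError(
            "need a 2-D matrix with at least 3 cells for correlations"
        )
    sd = X.std(axis=0)
    zero_var = sd == 0
    if np.all(zero_var):
        raise UndefinedStatisticError("all genes have zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[zero_var, :] = np.nan
    R[:, zero_var] = np.nan
    np.fill_diagonal(R, np.where(zero_var, np.nan, 1.0))
    R = np.clip(R, -1.0, 1.0)
    return PearsonResult(R=R, zero_variance=zero_var, gene_names=gene_names)


def eigvec_alignment(v_a: np.ndarray, v_b: np.ndarray) -> float:
    """Sign-invariant Euclidean distance between two directions.

    Both vectors are normalized to unit norm and the sign of ``v_b`` is
    chosen to minimize the distance (eigenvectors are defined up to a
    sign), so the result lies in [0, sqrt(2)].
    """
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if v_a.shape != v_b.shape or v_a.ndim != 1:
        raise ShapeError("vectors must be 1-D of equal length")
    na, nb = np.linalg.norm(v_a), np.linalg.norm(v_b)
    if na == 0 or nb == 0:
        raise DomainError("alignment of a zero vector is undefined")
    a, b = v_a / na, v_b / nb
    return float(min(np.linalg.norm(a - b), np.linalg.norm(a + b)))


def driver_responder_correlations(
    X: ExpressionMatrix, params: GRNParams
) -> pd.DataFrame:
    """Correlation of each responder with its own driver, sorted by alpha.

    Returns a frame with columns ``gene``, ``alpha``, ``driver``, ``r``;
    ``r`` is NaN when either gene has zero variance (e.g. noiseless
    simulations).
    """
    if X.gene_names != params.gene_names:
        raise DomainError("matrix gene names do not match the network's genes")
    if params.n_responders == 0:
        return pd.DataFrame(columns=["gene", "alpha", "driver", "r"])
    try:
        res = pearson_matrix(X)
        R = res.R
    except UndefinedStatisticError:
        # fully constant matrix (e.g. noiseless run): all undefined
        R = np.full((params.n_g, params.n_g), np.nan)
    rows = []
    for j in range(params.n_responders):
        d = int(params.driver_of[j])
        rows.append(
            {
                "gene": params.gene_names[j + 2],
                "alpha": float(params.alpha[j]),
                "driver": d,
                "r": float(R[j + 2, d - 1]),
            }
        )
    return (
        pd.DataFrame(rows).sort_values("alpha", kind="stable").reset_index(drop=True)
    )
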