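"""Stochastic two-driver toggle-switch gene regulatory network.

The simulated network consists of two mutually inhibiting "driver" genes
g1, g2 and ``n_g - 2`` downstream "responder" genes, each coupled to one
driver.  The deterministic core is

.. math::

    \\dot g_1 = -k_D g_1 + \\frac{m_1}{1 + g_2^2}, \\qquad
    \\dot g_2 = -k_D g_2 + \\frac{m_2}{1 + g_1^2},

a classic genetic toggle switch with Hill coefficient 2: varying the
synthesis scale ``m1`` (with ``m2`` fixed) drives the system through a
saddle-node structure with balanced bimodality at ``m1 = m2``, while
lowering the shared degradation rate ``k_D`` at ``m1 = m2 = 1`` produces
a supercritical pitchfork at ``k_D = 0.5``.

Responder ``i`` relaxes toward a Hill response of its driver ``d(i)``
interpolated between full activation and full inhibition by the coupling
strength ``alpha_i`` in [0, 1]:

.. math::

    \\dot g_i = -k_i g_i + m_{d(i)} \\left[ \\alpha_i
        \\frac{g_d^2}{1 + g_d^2} + (1 - \\alpha_i) \\frac{1}{1 + g_d^2}
        \\right].

Stochastic trajectories use an Euler scheme in which the next state of
each gene is drawn from a Gaussian centred on the deterministic update,
with a chemical-Langevin-style standard deviation
``sigma_i = sqrt(dt * (synthesis_i + degradation_i) / s)`` (birth and
death events contribute independent Poisson-like fluctuations; ``1/s``
is the overall noise scale), clamped at zero so expression stays
nonnegative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, root

from .containers import ExpressionMatrix
from .errors import (
    BracketingError,
    DomainError,
    InstabilityError,
    InvalidNetworkError,
)

__all__ = [
    "GRNParams",
    "FixedPoint",
    "build_network",
    "drift",
    "jacobian",
    "slowest_mode",
    "noise_diffusion",
    "find_driver_fixed_points",
    "critical_control",
    "simulate",
    "sweep",
]


@dataclass
class GRNParams:
    """Full parameterization of the simulated network.

    Genes ``0`` and ``1`` are the drivers; genes ``2 .. n_g-1`` are
    responders.  ``driver_of[j]`` is 1 or 2 for responder ``j`` (index
    ``j`` runs over responders only).
    """

    n_g: int = 102
    n_c: int = 100
    m1: float = 1.0
    m2: float = 1.0
    k_D: float = 1.0
    k_resp: np.ndarray = field(default_factory=lambda: np.ones(100))
    alpha: np.ndarray = field(default_factory=lambda: np.zeros(100))
    driver_of: np.ndarray = field(default_factory=lambda: np.ones(100, dtype=int))
    s: float = 20.0
    dt: float = 0.01
    n_steps: int = 20_000
    init_range: tuple[float, float] = (0.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_g < 2:
            raise InvalidNetworkError("need at least the two driver genes (n_g >= 2)")
        if self.n_c < 2:
            raise InvalidNetworkError("need at least two cells (n_c >= 2)")
        self.k_resp = np.atleast_1d(np.asarray(self.k_resp, dtype=float))[: self.n_responders]
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))[: self.n_responders]
        self.driver_of = np.atleast_1d(np.asarray(self.driver_of, dtype=int))[: self.n_responders]
        n_r = self.n_responders
        if not (len(self.k_resp) == len(self.alpha) == len(self.driver_of) == n_r):
            raise InvalidNetworkError(
                f"responder arrays must have length n_g - 2 = {n_r}"
            )
        for name, val in (("m1", self.m1), ("m2", self.m2), ("k_D", self.k_D),
                          ("s", self.s), ("dt", self.dt)):
            if val <= 0:
                raise InvalidNetworkError(f"{name} must be positive, got {val}")
        if n_r and np.any(self.k_resp <= 0):
            raise InvalidNetworkError("responder degradation rates must be positive")
        if n_r and (np.any(self.alpha < 0) or np.any(self.alpha > 1)):
            raise InvalidNetworkError("coupling strengths alpha must lie in [0, 1]")
        if n_r and not np.all(np.isin(self.driver_of, (1, 2))):
            raise InvalidNetworkError("driver_of entries must be 1 or 2")
        lo, hi = self.init_range
        if lo < 0 or hi < lo:
            raise InvalidNetworkError("init_range must be a nonnegative interval")
        if self.n_steps < 1:
            raise InvalidNetworkError("n_steps must be >= 1")

    @property
    def n_responders(self) -> int:
        return self.n_g - 2

    @property
    def gene_names(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_g)]

    @property
    def m_of_responder(self) -> np.ndarray:
        """Synthesis scale of each responder's driver."""
        return np.where(self.driver_of == 1, self.m1, self.m2)


@dataclass
class FixedPoint:
    """A fixed point of the deterministic network."""

    state: np.ndarray
    stable: bool
    lambda_d: float

    @property
    def drivers(self) -> tuple[float, float]:
        return float(self.state[0]), float(self.state[1])


def build_network(
    n_g: int = 102,
    seed: int = 0,
    alpha_sampling="uniform",
    k_resp_value: float = 1.0,
    **overrides,
) -> GRNParams:
    """Construct a seeded network parameterization.

    Responders are assigned alternately to the two drivers (balanced:
    half respond to g1, half to g2) and their coupling strengths
    ``alpha_i`` are drawn uniformly on [0, 1] from a generator seeded
    with ``seed``, so the same seed always yields the same network.

    Parameters
    ----------
    alpha_sampling
        ``"uniform"`` (default), a constant float applied to every
        responder, or a callable ``f(rng, n) -> array``.
    overrides
        Any further :class:`GRNParams` field (``m1``, ``k_D``, ...).
    """
    if n_g < 2:
        raise InvalidNetworkError(f"n_g must be >= 2, got {n_g}")
    n_r = n_g - 2
    rng = np.random.default_rng(seed)
    if alpha_sampling == "uniform":
        alpha = rng.uniform(0.0, 1.0, n_r)
    elif callable(alpha_sampling):
        alpha = np.asarray(alpha_sampling(rng, n_r), dtype=float)
    else:
        alpha = np.full(n_r, float(alpha_sampling))
    driver_of = np.where(np.arange(n_r) % 2 == 0, 1, 2)
    return GRNParams(
        n_g=n_g,
        seed=seed,
        alpha=alpha,
        driver_of=driver_of,
        k_resp=np.full(n_r, float(k_resp_value)),
        **overrides,
    )


def _synthesis(state: np.ndarray, params: GRNParams) -> np.ndarray:
    """Per-gene synthesis rates; ``state`` may be (n_g,) or (n_c, n_g)."""
    g1 = state[..., 0]
    g2 = state[..., 1]
    syn = np.empty_like(state)
    syn[..., 0] = params.m1 / (1.0 + g2**2)
    syn[..., 1] = params.m2 / (1.0 + g1**2)
    if params.n_responders:
        gd = state[..., np.where(params.driver_of == 1, 0, 1)]
        denom = 1.0 + gd**2
        syn[..., 2:] = params.m_of_responder * (
            params.alpha * gd**2 / denom + (1.0 - params.alpha) / denom
        )
    return syn


def _degradation_rates(params: GRNParams) -> np.ndarray:
    k = np.empty(params.n_g)
    k[0] = k[1] = params.k_D
    k[2:] = params.k_resp
    return k


def drift(state: np.ndarray, params: GRNParams) -> np.ndarray:
    """Deterministic rate of change dg/dt at ``state``.

    ``state`` may be a single (n_g,) vector or a batch (n_c, n_g).
    """
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != params.n_g:
        raise DomainError(
            f"state has {state.shape[-1]} genes, network has {params.n_g}"
        )
    if np.any(state < 0):
        raise DomainError("expression state must be nonnegative")
    return _synthesis(state, params) - _degradation_rates(params) * state


def jacobian(state: np.ndarray, params: GRNParams) -> np.ndarray:
    """Analytic Jacobian of :func:`drift` at ``state``.

    Diagonal entries are the negated degradation rates.  The only
    off-diagonal structure is the mutual inhibition of the driver block
    and, for each responder, the sensitivity to its own driver, so the
    matrix is block lower triangular up to the 2x2 driver core.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (params.n_g,):
        raise DomainError(f"state must have shape ({params.n_g},)")
    if np.any(state < 0):
        raise DomainError("expression state must be nonnegative")
    g1, g2 = state[0], state[1]
    J = np.diag(-_degradation_rates(params))
    J[0, 1] = -2.0 * params.m1 * g2 / (1.0 + g2**2) ** 2
    J[1, 0] = -2.0 * params.m2 * g1 / (1.0 + g1**2) ** 2
    if params.n_responders:
        dcol = np.where(params.driver_of == 1, 0, 1)
        gd = state[dcol]
        # d/d(gd) of  m [a gd^2 + (1-a)] / (1+gd^2)  =  m (2a-1) 2 gd / (1+gd^2)^2
        J[np.arange(2, params.n_g), dcol] = (
            params.m_of_responder
            * (2.0 * params.alpha - 1.0)
            * 2.0
            * gd
            / (1.0 + gd**2) ** 2
        )
    return J


def slowest_mode(J: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest-real-part eigenvalue of ``J`` and its (real, unit) eigenvector."""
    vals, vecs = np.linalg.eig(J)
    i = int(np.argmax(vals.real))
    v = np.real(vecs[:, i])
    v = v / np.linalg.norm(v)
    # deterministic sign: largest-magnitude component positive
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return float(vals[i].real), v


def noise_diffusion(state: np.ndarray, params: GRNParams) -> np.ndarray:
    """Diagonal of the diffusion matrix, (synthesis + degradation) / s.

    This is the continuous-time noise covariance Q implied by the
    per-step sampling noise of :func:`simulate` (sigma_i^2 / dt), used
    as the default Q in Lyapunov solves.
    """
    state = np.asarray(state, dtype=float)
    return (_synthesis(state, params) + _degradation_rates(params) * state) / params.s


def responder_steady_state(g1: float, g2: float, params: GRNParams) -> np.ndarray:
    """Closed-form responder values given driver values."""
    if params.n_responders == 0:
        return np.empty(0)
    gd = np.where(params.driver_of == 1, g1, g2)
    denom = 1.0 + gd**2
    syn = params.m_of_responder * (
        params.alpha * gd**2 / denom + (1.0 - params.alpha) / denom
    )
    return syn / params.k_resp


def _driver_fixed_points_2d(
    params: GRNParams, n_grid: int = 25, tol: float = 1e-10
) -> list[tuple[float, float]]:
    """Multi-start root finding on the 2-D driver core."""
    m1, m2, k = params.m1, params.m2, params.k_D

    def core(x):
        g1, g2 = x
        return [
            -k * g1 + m1 / (1.0 + g2**2),
            -k * g2 + m2 / (1.0 + g1**2),
        ]

    g_max = max(m1, m2) / k
    pts: list[tuple[float, float]] = []
    grid = np.linspace(0.0, g_max, n_grid)
    for a in grid:
        for b in grid:
            sol = root(core, [a, b], method="hybr", tol=1e-12)
            if not sol.success:
                continue
            g1, g2 = sol.x
            if g1 < -1e-9 or g2 < -1e-9:
                continue
            if max(abs(v) for v in core([g1, g2])) > tol:
                continue
            g1, g2 = max(g1, 0.0), max(g2, 0.0)
            if not any(abs(g1 - p) < 1e-6 and abs(g2 - q) < 1e-6 for p, q in pts):
                pts.append((g1, g2))
    if not pts:
        raise BifurcationSolverError(params)
    return sorted(pts)


class BifurcationSolverError(DomainError):
    """Raised when fixed-point enumeration fails (should not occur)."""

    def __init__(self, params):
        super().__init__(
            f"fixed-point search failed for m1={params.m1}, m2={params.m2}, "
            f"k_D={params.k_D}"
        )


def find_driver_fixed_points(
    params: GRNParams, n_grid: int = 25, tol: float = 1e-10
) -> list[FixedPoint]:
    """Enumerate fixed points of the full network.

    The 2-D driver core is solved by multi-start root finding on a grid
    over ``[0, max(m1, m2)/k_D]``; responder values then follow in
    closed form.  Points are deduplicated within 1e-6 and labelled
    stable/unstable by the sign of the largest Jacobian eigenvalue.
    """
    out = []
    for g1, g2 in _driver_fixed_points_2d(params, n_grid=n_grid, tol=tol):
        state = np.concatenate([[g1, g2], responder_steady_state(g1, g2, params)])
        lam, _ = slowest_mode(jacobian(state, params))
        out.append(FixedPoint(state=state, stable=lam < 0, lambda_d=lam))
    return out


def _symmetric_driver_value(m: float, k: float) -> float:
    """Solve k*g*(1+g^2) = m for the symmetric driver fixed point."""
    g_hi = max(m / k, 1.0)
    return brentq(lambda g: k * g * (1.0 + g**2) - m, 0.0, g_hi, xtol=1e-14)


def _symmetric_lambda_d(params: GRNParams) -> float:
    """lambda_d at the symmetric fixed point (requires m1 == m2)."""
    g = _symmetric_driver_value(params.m1, params.k_D)
    state = np.concatenate(
        [[g, g], responder_steady_state(g, g, params)]
    )
    lam, _ = slowest_mode(jacobian(state, params))
    return lam


def _middle_saddle_asymmetry(params: GRNParams) -> float:
    """g1* - g2* of the middle (saddle) driver branch.

    Inside the bistable strip the middle saddle moves continuously with
    m1 and is exactly symmetric (g1* = g2*) when m1 = m2, by the
    exchange symmetry of the toggle switch; its sign change locates the
    balanced-bimodality point of the saddle-node transition.  Outside
    the strip the unique fixed point carries the same sign (g1* < g2*
    below the balanced point, g1* > g2* above), so wide brackets remain
    valid.
    """
    pts = _driver_fixed_points_2d(params)
    g1, g2 = pts[len(pts) // 2]
    return g1 - g2


def critical_control(
    params: GRNParams,
    control: str,
    bracket: tuple[float, float],
    tol: float = 1e-8,
    max_iter: int = 200,
) -> float:
    """Locate the critical value of a control parameter by bisection.

    ``control="k_D"`` (pitchfork): tracks the symmetric fixed point of
    the driver core (requires ``m1 == m2``) and bisects on the sign of
    the largest Jacobian eigenvalue ``lambda_d`` until ``|lambda_d| <
    tol``; returns the degradation rate at which linear stability is
    lost (0.5 for m1 = m2 = 1).

    ``control="m1"`` (saddle-node): bisects on the asymmetry
    ``g1* - g2*`` of the middle saddle branch, returning the balanced
    point of the bistable strip at which the steady-state distribution
    is maximally bimodal (m1 = m2 exactly, e.g. 3 for m2 = 3).

    Raises :class:`BracketingError` when the indicator does not change
    sign over ``bracket``.
    """
    if tol <= 0:
        raise DomainError("tol must be positive")
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise DomainError("bracket must be an increasing pair")

    if control == "k_D":
        if params.m1 != params.m2:
            raise DomainError(
                "pitchfork tracking requires a symmetric core (m1 == m2)"
            )
        indicator = lambda v: _symmetric_lambda_d(replace(params, k_D=v))
    elif control == "m1":
        indicator = lambda v: _middle_saddle_asymmetry(replace(params, m1=v))
    else:
        raise DomainError(f"unknown control parameter {control!r}")

    f_lo, f_hi = indicator(lo), indicator(hi)
    if np.sign(f_lo) == np.sign(f_hi):
        raise BracketingError(
            f"indicator does not change sign over [{lo}, {hi}] "
            f"(f({lo})={f_lo:.3g}, f({hi})={f_hi:.3g})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = indicator(mid)
        if abs(f_mid) < tol or (hi - lo) < 1e-15:
            return mid
        if np.sign(f_mid) == np.sign(f_lo):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)


def simulate(params: GRNParams, check_drift: float | None = None) -> ExpressionMatrix:
    """Integrate the stochastic network and return the final-step matrix.

    Each of ``n_c`` cells is initialized uniformly in ``init_range`` and
    integrated independently for ``n_steps`` Euler steps: the next state
    is sampled from ``Normal(g + dt * drift, sigma)`` with the
    chemical-Langevin sigma described in the module docstring, then
    clamped at zero.  The returned matrix is the last timestep — the
    steady-state expression snapshot across the cell population.

    ``check_drift``, if given, warns when the mean drift norm over the
    final 1% of steps exceeds it (equilibration check).
    """
    rng = np.random.default_rng(params.seed)
    lo, hi = params.init_range
    G = rng.uniform(lo, hi, size=(params.n_c, params.n_g))
    k = _degradation_rates(params)
    sqrt_dt_over_s = np.sqrt(params.dt / params.s)
    tail_start = params.n_steps - max(1, params.n_steps // 100)
    tail_norms = []
    for t in range(params.n_steps):
        syn = _synthesis(G, params)
        deg = k * G
        dG = syn - deg
        mu = G + params.dt * dG
        sigma = sqrt_dt_over_s * np.sqrt(syn + deg)
        G = np.maximum(rng.normal(mu, sigma), 0.0)
        if not np.all(np.isfinite(G)):
            raise InstabilityError(
                f"non-finite expression at integration step {t}"
            )
        if check_drift is not None and t >= tail_start:
            tail_norms.append(np.linalg.norm(dG, axis=1).mean())
    if check_drift is not None and np.mean(tail_norms) > check_drift:
        warnings.warn(
            f"mean drift norm over final 1% of steps "
            f"({np.mean(tail_norms):.3g}) exceeds {check_drift}; "
            "the simulation may not be equilibrated",
            stacklevel=2,
        )
    return ExpressionMatrix(
        values=G,
        cell_ids=[f"cell_{i:04d}" for i in range(params.n_c)],
        gene_names=params.gene_names,
    )


def sweep(
    params: GRNParams, control: str, grid
) -> list[tuple[float, ExpressionMatrix]]:
    """One independent simulation per value of ``control`` on ``grid``.

    Seeds are derived deterministically from the base seed and the grid
    index, so the sweep is reproducible and each point independent.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise DomainError("grid must be sorted ascending")
    if control not in ("m1", "m2", "k_D", "s"):
        raise DomainError(f"unknown control parameter {control!r}")
    out = []
    for i, value in enumerate(grid):
        p = replace(params, **{control: float(value)},
                    seed=(params.seed + 10_007 * (i + 1)) % (2**31))
        out.append((float(value), simulate(p)))
    return out
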