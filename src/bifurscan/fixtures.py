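"""Synthetic trajectories with planted transitions.

The generator emulates the statistical structure of a bifurcating
expression trajectory without simulating dynamics: cells are drawn from
a Gaussian with baseline isotropic noise around a positive mean, plus a
rank-1 component along a planted unit direction whose magnitude follows
the transition class —

* ``one-to-one``: a localized bump of extra variance centred on the
  planted bin (the covariance spike of a state jump);
* ``one-to-many``: a linear ramp of variance from the planted bin
  onward (a branch opening continuously);
* ``step-like``: a constant level shift from the planted bin onward
  (a noise-induced state switch);
* ``none``: pure isotropic noise.

Ground truth (direction, planted bin, cell-rank centre) is returned so
tests can assert both detection and direction recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ExpressionMatrix
from .errors import DomainError
from .trajectory import bin_by_pseudotime

__all__ = ["FixtureSpec", "Fixture", "generate_fixture"]

_CLASSES = ("one-to-one", "one-to-many", "step-like", "none")


@dataclass
class FixtureSpec:
    """Specification of a planted-transition trajectory."""

    n_cells: int = 3000
    n_genes: int = 60
    bin_size: int = 200
    overlap: float = 0.5
    transition_bin: int = 15  # 1-based, as in scan outputs
    transition_class: str = "one-to-one"
    effect_size: float = 10.0  # rank-1 sd at peak, in units of noise_scale
    noise_scale: float = 1.0
    baseline: float = 10.0  # keeps expression values positive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_class not in _CLASSES:
            raise DomainError(
                f"transition_class must be one of {_CLASSES}, "
                f"got {self.transition_class!r}"
            )
        if self.effect_size < 0:
            raise DomainError("effect_size must be >= 0")
        if self.noise_scale <= 0:
            raise DomainError("noise_scale must be positive")
        n_bins = (self.n_cells - self.bin_size) // max(
            1, int(round(self.bin_size * (1 - self.overlap)))
        ) + 1
        if not 1 <= self.transition_bin <= n_bins:
            raise DomainError(
                f"transition_bin {self.transition_bin} outside 1..{n_bins}"
            )


@dataclass
class Fixture:
    """A generated trajectory plus its ground truth."""

    matrix: ExpressionMatrix
    spec: FixtureSpec
    direction: np.ndarray  # planted unit direction in gene space
    center_rank: int  # cell rank at the centre of the planted bin


def _signal_profile(spec: FixtureSpec, center: int) -> np.ndarray:
    """Per-cell standard deviation of the planted rank-1 component."""
    r = np.arange(spec.n_cells, dtype=float)
    peak = spec.effect_size * spec.noise_scale
    if spec.transition_class == "none" or spec.effect_size == 0:
        return np.zeros(spec.n_cells)
    if spec.transition_class == "one-to-one":
        width = spec.bin_size / 4.0
        return peak * np.exp(-0.5 * ((r - center) / width) ** 2)
    if spec.transition_class == "one-to-many":
        ramp = np.clip((r - center) / max(1.0, spec.n_cells - 1 - center), 0, 1)
        return peak * ramp
    # step-like
    return np.where(r >= center, peak, 0.0)


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Draw a planted-transition trajectory from ``spec``.

    Pseudotime is the cell rank (1..n_cells).  The planted direction is
    a seeded random unit vector; each cell is ``baseline +
    noise_scale * N(0, I) + a_r * direction`` with ``a_r ~ N(0,
    profile(r)^2)``, clipped at zero to respect nonnegativity.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.normal(size=spec.n_genes)
    u /= np.linalg.norm(u)
    bins = bin_by_pseudotime(spec.n_cells, spec.bin_size, spec.overlap)
    b = spec.transition_bin - 1
    center = int(round(np.mean([bins.bins[b][0], bins.bins[b][-1]])))
    profile = _signal_profile(spec, center)
    V = spec.baseline + spec.noise_scale * rng.normal(
        size=(spec.n_cells, spec.n_genes)
    )
    amps = rng.normal(scale=1.0, size=spec.n_cells) * profile
    V = np.clip(V + amps[:, None] * u[None, :], 0.0, None)
    matrix = ExpressionMatrix(
        values=V,
        cell_ids=[f"cell_{i:05d}" for i in range(spec.n_cells)],
        gene_names=[f"gene_{j:03d}" for j in range(spec.n_genes)],
        pseudotime=np.arange(1, spec.n_cells + 1, dtype=float),
    )
    return Fixture(matrix=matrix, spec=spec, direction=u, center_rank=center)
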