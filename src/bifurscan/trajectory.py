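"""Pseudotime trajectory scan.

The pipeline characterizing bifurcations in high-dimensional temporal
expression data:

1. normalize cells (rows) of the expression matrix;
2. bin cells along pseudotime into overlapping bins;
3. compute the principal covariance eigenvalue omega_1 in every bin;
4. compare against a gene-shuffling permutation null that preserves
   each gene's within-bin marginal but destroys gene-gene correlations;
5. classify the omega_1(tau) shape: an isolated spike indicates a
   one-to-one (maturation-like) transition, a sustained increase a
   one-to-many (decision-like) transition, and a step between two
   plateaus a noise-induced state switch.

A dynamical-network-biomarker (DNB) composite index over a candidate
gene set is provided as an established benchmark for the eigenvalue
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .ctl_core import covariance_eig, pearson_matrix
from .errors import ConfigError, DomainError, ShapeError, UndefinedStatisticError

__all__ = [
    "BinnedTrajectory",
    "OmegaTrajectory",
    "TransitionReport",
    "Thresholds",
    "normalize_cells",
    "bin_by_pseudotime",
    "omega_trajectory",
    "null_trajectory",
    "classify_transitions",
    "dnb_order_parameter",
    "scan",
]


@dataclass
class BinnedTrajectory:
    """Ordered, overlapping cell bins along pseudotime.

    Bin labels are 1-based.  All bins except the last contain exactly
    ``bin_size`` cells; the last absorbs trailing cells and has
    ``bin_size <= size < bin_size + step``.
    """

    bins: list[np.ndarray]  # cell indices per bin, pseudotime-sorted
    mean_pseudotime: np.ndarray
    bin_size: int
    overlap: float

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def labels(self) -> np.ndarray:
        return np.arange(1, self.n_bins + 1)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(b) for b in self.bins])

    @property
    def step(self) -> int:
        return max(1, int(round(self.bin_size * (1.0 - self.overlap))))


@dataclass
class OmegaTrajectory:
    """Per-bin principal covariance eigenvalue with its permutation null."""

    bins: BinnedTrajectory
    omega1: np.ndarray
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    dnb: np.ndarray | None = None

    @property
    def omega1_shifted(self) -> np.ndarray:
        return self.omega1 - self.omega1.min()

    @property
    def null_mean_shifted(self) -> np.ndarray | None:
        if self.null_mean is None:
            return None
        return self.null_mean - self.null_mean.min()

    @property
    def z(self) -> np.ndarray | None:
        """Per-bin z-score of omega1 against its own permutation null."""
        if self.null_mean is None:
            return None
        sd = np.where(self.null_sd > 0, self.null_sd, np.nan)
        return (self.omega1 - self.null_mean) / sd

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "bin": self.bins.labels,
                "n_cells": self.bins.sizes,
                "mean_pseudotime": self.bins.mean_pseudotime,
                "omega1": self.omega1,
                "omega1_shifted": self.omega1_shifted,
            }
        )
        if self.null_mean is not None:
            df["null_mean"] = self.null_mean
            df["null_sd"] = self.null_sd
            df["z"] = self.z
        if self.dnb is not None:
            df["dnb"] = self.dnb
        return df


@dataclass
class TransitionEvent:
    bin: int
    kind: str  # "one-to-one" | "one-to-many" | "step-like"
    z: float
    window: tuple[int, int]  # supporting bin range (inclusive, 1-based)


@dataclass
class TransitionReport:
    """Detected transitions, sorted by bin."""

    events: list[TransitionEvent]

    @property
    def classification(self) -> str:
        return self.events[0].kind if self.events else "none"

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "events": [
                {
                    "bin": int(e.bin),
                    "kind": e.kind,
                    "z": None if np.isnan(e.z) else float(e.z),
                    "window": [int(e.window[0]), int(e.window[1])],
                }
                for e in self.events
            ],
        }


@dataclass
class Thresholds:
    """Detection thresholds for :func:`classify_transitions`.

    ``z_spike``: minimum z at a one-to-one spike; ``z_onset``: run
    threshold for a one-to-many onset (also the return level for a
    spike); ``run_length``: minimum run of elevated bins for an onset;
    ``spike_return_window``: bins within which a spike must fall back
    below ``z_onset``; ``step_gap``/``step_slope`` control the
    step-like (noise-induced transition) change-point test.
    """

    z_spike: float = 5.0
    z_onset: float = 2.0
    run_length: int = 10
    spike_return_window: int = 5
    step_gap: float = 4.0
    step_slope: float = 0.15

    def validate(self) -> None:
        for name in ("z_spike", "z_onset", "step_gap", "step_slope"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be positive")
        for name in ("run_length", "spike_return_window"):
            if getattr(self, name) < 1:
                raise ConfigError(f"threshold {name} must be >= 1")


def normalize_cells(G, mode: str = "sum"):
    """Row-normalize an expression matrix.

    ``mode="sum"`` scales every cell to unit total expression (the
    default reading of cell normalization); ``"median"`` scales cells
    to the median total count; ``"none"`` returns a copy.  All-zero
    rows cannot be normalized and raise an error naming the cells.
    """
    if mode not in ("sum", "median", "none"):
        raise ConfigError(f"unknown normalization mode {mode!r}")
    is_em = isinstance(G, ExpressionMatrix)
    V = G.values if is_em else np.asarray(G, dtype=float)
    if mode == "none":
        out = V.copy()
    else:
        totals = V.sum(axis=1)
        zero = totals == 0
        if np.any(zero):
            ids = (
                [G.cell_ids[i] for i in np.where(zero)[0]]
                if is_em
                else list(np.where(zero)[0])
            )
            raise DomainError(f"cannot normalize all-zero cells: {ids[:10]}")
        target = 1.0 if mode == "sum" else float(np.median(totals))
        out = V * (target / totals)[:, None]
    if is_em:
        return ExpressionMatrix(
            values=out,
            cell_ids=list(G.cell_ids),
            gene_names=list(G.gene_names),
            pseudotime=None if G.pseudotime is None else G.pseudotime.copy(),
        )
    return out


def bin_by_pseudotime(pseudotime, bin_size: int, overlap: float = 0.5) -> BinnedTrajectory:
    """Bin cells along pseudotime into overlapping, ordered bins.

    ``pseudotime`` may be an integer cell count (cells are then taken
    in rank order), a 1-D array of pseudotime values (ties broken by
    stable input order), or an :class:`ExpressionMatrix` carrying
    pseudotime.  Bins of ``bin_size`` cells start every ``step =
    round(bin_size * (1 - overlap))`` cells while a full bin fits; the
    final bin is extended to absorb trailing cells.
    """
    if isinstance(pseudotime, ExpressionMatrix):
        if pseudotime.pseudotime is None:
            raise DomainError("expression matrix carries no pseudotime")
        pseudotime = pseudotime.pseudotime
    if np.isscalar(pseudotime):
        n = int(pseudotime)
        order = np.arange(n)
        pt = order.astype(float) + 1.0
    else:
        pt = np.asarray(pseudotime, dtype=float)
        if pt.ndim != 1:
            raise ShapeError("pseudotime must be 1-D")
        n = pt.size
        order = np.argsort(pt, kind="stable")
        pt = pt[order]
    if not 0 <= overlap < 1:
        raise ConfigError(f"overlap must be in [0, 1), got {overlap}")
    if bin_size < 2:
        raise ConfigError("bin_size must be >= 2")
    if n < bin_size:
        raise DomainError(
            f"{n} cells cannot fill a bin of {bin_size}; use a smaller bin_size"
        )
    step = max(1, int(round(bin_size * (1.0 - overlap))))
    n_bins = (n - bin_size) // step + 1
    bins = []
    for b in range(n_bins):
        start = b * step
        stop = start + bin_size if b < n_bins - 1 else n
        bins.append(order[start:stop])
    means = np.array([pt[b * step: (b * step + len(bins[b]))].mean() for b in range(n_bins)])
    return BinnedTrajectory(
        bins=bins, mean_pseudotime=means, bin_size=bin_size, overlap=overlap
    )


def omega_trajectory(G, bins: BinnedTrajectory) -> OmegaTrajectory:
    """Principal covariance eigenvalue in every pseudotime bin.

    The matrix is used as given; apply :func:`normalize_cells` first
    when cell normalization is wanted (the :func:`scan` pipeline does).
    """
    V = G.values if isinstance(G, ExpressionMatrix) else np.asarray(G, dtype=float)
    omega1 = np.empty(bins.n_bins)
    for i, idx in enumerate(bins.bins):
        if len(idx) < 2:
            raise UndefinedStatisticError(f"bin {i + 1} has fewer than 2 cells")
        omega1[i] = covariance_eig(V[idx], k=1).omega1
    return OmegaTrajectory(bins=bins, omega1=omega1)


def null_trajectory(
    G, bins: BinnedTrajectory, n_reps: int = 20, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation null of the omega_1 trajectory.

    For each replicate, every gene column is permuted independently
    across the cells of each bin: the within-bin marginal distribution
    of every gene is preserved exactly while all gene-gene correlations
    are destroyed.  Returns the per-bin mean and (ddof=1) standard
    deviation of the null omega_1 over replicates.
    """
    if n_reps < 2:
        raise ConfigError("need at least 2 null replicates")
    V = G.values if isinstance(G, ExpressionMatrix) else np.asarray(G, dtype=float)
    rng = np.random.default_rng(seed)
    null = np.empty((bins.n_bins, n_reps))
    for i, idx in enumerate(bins.bins):
        sub = V[idx]
        for r in range(n_reps):
            # independent permutation of every gene column at once
            keys = rng.random(sub.shape)
            perm = np.take_along_axis(sub, np.argsort(keys, axis=0), axis=0)
            null[i, r] = covariance_eig(perm, k=1).omega1
    return null.mean(axis=1), null.std(axis=1, ddof=1)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (start, stop) index pairs (stop exclusive)."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, mask.size))
    return runs


def classify_transitions(
    traj: OmegaTrajectory, thresholds: Thresholds | None = None
) -> TransitionReport:
    """Classify the shape of an omega_1 trajectory against its null.

    See :class:`Thresholds` for the decision rules.  Requires the
    trajectory to carry a permutation null (z-scores).
    """
    th = thresholds or Thresholds()
    th.validate()
    z = traj.z
    if z is None:
        raise DomainError("trajectory has no null; run null_trajectory first")
    z = np.where(np.isfinite(z), z, 0.0)
    n = z.size
    if n < 5:
        raise DomainError("need at least 5 bins to classify transitions")
    events: list[TransitionEvent] = []

    # one-to-one spikes: local maxima above z_spike that are isolated —
    # z falls back below z_onset within the return window on both sides
    # (an unreturning rise is an onset or a step, not a spike)
    spike_bins = set()
    for i in range(n):
        if z[i] < th.z_spike:
            continue
        left = z[i - 1] if i > 0 else -np.inf
        right = z[i + 1] if i < n - 1 else -np.inf
        if z[i] < left or z[i] < right:
            continue
        after = z[i + 1: i + 1 + th.spike_return_window]
        before = z[max(0, i - th.spike_return_window): i]
        if not after.size or not np.any(after < th.z_onset):
            continue
        if before.size and not np.any(before < th.z_onset):
            continue
        ret = i + 1 + int(np.argmax(after < th.z_onset))
        events.append(
            TransitionEvent(
                bin=i + 1, kind="one-to-one", z=float(z[i]), window=(i + 1, ret + 1)
            )
        )
        spike_bins.add(i)

    # one-to-many onsets: long elevated runs with nonnegative trend
    for start, stop in _runs_above(z >= th.z_onset):
        if stop - start < th.run_length:
            continue
        if any(start <= b < stop for b in spike_bins):
            continue
        slope = np.polyfit(np.arange(start, stop), z[start:stop], 1)[0]
        if slope < 0:
            continue
        events.append(
            TransitionEvent(
                bin=start + 1,
                kind="one-to-many",
                z=float(z[start]),
                window=(start + 1, stop),
            )
        )

    # step-like: best single change-point between two low-slope plateaus
    # at different levels (noise-induced transition signature)
    if not events:
        best = None
        for c in range(2, n - 2):
            lo, hi = z[:c], z[c:]
            gap = abs(hi.mean() - lo.mean())
            if gap < th.step_gap:
                continue
            s_lo = abs(np.polyfit(np.arange(lo.size), lo, 1)[0])
            s_hi = abs(np.polyfit(np.arange(hi.size), hi, 1)[0])
            if max(s_lo, s_hi) > th.step_slope * gap:
                continue
            if best is None or gap > best[1]:
                best = (c, gap)
        if best is not None:
            c, gap = best
            events.append(
                TransitionEvent(
                    bin=c + 1, kind="step-like", z=float(z[c]), window=(1, n)
                )
            )

    events.sort(key=lambda e: e.bin)
    return TransitionReport(events=events)


def dnb_order_parameter(
    G_bin, dnb_genes, gene_names: list[str] | None = None, eps: float = 1e-6
) -> float:
    """Dynamical-network-biomarker composite index for one bin.

    ``I = SD_avg(DNB) * |PCC|_avg(within DNB) / (|PCC|_avg(DNB, rest) +
    eps)``: the average standard deviation of the candidate genes times
    their average absolute pairwise correlation, divided by their
    average absolute correlation with all other genes.  The index rises
    sharply when the candidate group both fluctuates and co-fluctuates
    near a critical transition.  Undefined (zero-variance) correlations
    are excluded from the averages.
    """
    if isinstance(G_bin, ExpressionMatrix):
        gene_names = gene_names or G_bin.gene_names
        V = G_bin.values
    else:
        V = np.asarray(G_bin, dtype=float)
    if gene_names is None:
        raise DomainError("gene_names are required to resolve the DNB set")
    dnb_genes = list(dnb_genes)
    name_set = set(gene_names)
    missing = [g for g in dnb_genes if g not in name_set]
    if missing:
        raise DomainError(f"DNB genes not in matrix: {missing[:10]}")
    in_dnb = np.isin(np.asarray(gene_names), dnb_genes)
    if not in_dnb.any() or in_dnb.all():
        raise DomainError("DNB set must be a nonempty proper subset of the genes")
    res = pearson_matrix(V)
    absR = np.abs(res.R)
    inner = absR[np.ix_(in_dnb, in_dnb)]
    iu = np.triu_indices_from(inner, k=1)
    inner_vals = inner[iu]
    cross_vals = absR[np.ix_(in_dnb, ~in_dnb)].ravel()
    inner_mean = np.nanmean(inner_vals) if np.any(np.isfinite(inner_vals)) else 0.0
    cross_mean = np.nanmean(cross_vals) if np.any(np.isfinite(cross_vals)) else 0.0
    sd_avg = V[:, in_dnb].std(axis=0, ddof=1).mean()
    return float(sd_avg * inner_mean / (cross_mean + eps))


def scan(
    G: ExpressionMatrix,
    bin_size: int,
    overlap: float = 0.5,
    normalization: str = "sum",
    n_null_reps: int = 20,
    seed: int = 0,
    dnb_genes=None,
    thresholds: Thresholds | None = None,
) -> tuple[OmegaTrajectory, TransitionReport]:
    """Full trajectory scan: normalize, bin, omega_1, null, classify."""
    Gn = normalize_cells(G, mode=normalization)
    bins = bin_by_pseudotime(G, bin_size=bin_size, overlap=overlap)
    traj = omega_trajectory(Gn, bins)
    traj.null_mean, traj.null_sd = null_trajectory(
        Gn, bins, n_reps=n_null_reps, seed=seed
    )
    if dnb_genes is not None:
        traj.dnb = np.array(
            [
                dnb_order_parameter(Gn.values[idx], dnb_genes, Gn.gene_names)
                for idx in bins.bins
            ]
        )
    report = classify_transitions(traj, thresholds)
    return traj, report
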