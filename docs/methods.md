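# Methods

This note documents the models, numerical choices and known limitations
behind `bifurscan`. It is the reference for *why* the defaults are what
they are; the README covers *how* to run things.

## The covariance-eigendecomposition framework

A population of cells measured at one developmental moment is treated
as statistical replicates of a transcriptomic state fluctuating around
a fixed point of an (unknown) smooth dynamical system
`dg/dt = f(g)`. If the molecular dynamics are Markovian and fast
compared with cell-fate change, the deviations `X = G − g*` follow a
linear Ornstein–Uhlenbeck process with Jacobian `J = ∂f/∂g|_{g*}` and
diagonal noise covariance `Q`. Stationarity implies the continuous-time
Lyapunov equation

```
J C + C Jᵀ + Q = 0        (C = gene–gene covariance)
```

solved here by Bartels–Stewart (`scipy.linalg.solve_continuous_lyapunov`;
our convention fixes the noise term as written, with no extra factor on
`Q`). Writing `J = P Λ P⁻¹`, the elementwise solution shows that as the
largest Jacobian eigenvalue `λ_d → 0⁻` the term associated with the slow
mode dominates, so:

1. the largest covariance eigenvalue `ω₁` diverges (finite sampling
   regularizes it to a large spike);
2. the principal covariance eigenvector `ŝ₁` converges, up to sign, to
   the slow Jacobian eigenvector `v_d` — the direction of the
   bifurcation;
3. pairwise Pearson correlations `R_ij` with nonzero loadings on `v_d`
   expand toward ±1.

These three observable signatures are what the trajectory scan tests
for. They require only that cells are sampled near steady state; they
do not require knowing `f`, and `J` need not be symmetric.

`ω₁`/`ŝ₁` are computed from the reduced SVD of the column-centred
matrix (`ω_i = σ_i²/(n_c − 1)`, unbiased divisor; the paper-agnostic
choice of divisor is ours). Eigenvector sign is fixed by making the
largest-magnitude loading positive; every comparison that matters is
sign-invariant anyway (`eigvec_alignment` flips signs to minimize
distance).

## The validation network

The simulator implements a two-driver toggle switch with `n_g − 2`
passive responders:

```
dg₁/dt = −k_D g₁ + m₁/(1 + g₂²)
dg₂/dt = −k_D g₂ + m₂/(1 + g₁²)
dg_i/dt = −k_i g_i + m_d(i) [ α_i g_d²/(1+g_d²) + (1−α_i)/(1+g_d²) ]
```

* **Hill exponent 2.** Chosen because it reproduces the analytic
  pitchfork threshold `k_Dc = 0.5` at `m₁ = m₂ = 1` exactly (symmetric
  point `g* = 1`, driver block `[[−½,−½],[−½,−½]]`, `λ_d = 0`).
* **Responder coupling.** `α_i = 0` is full inhibition, `α_i = 1` full
  activation, linearly interpolated; the synthesis scale is the
  driver's own `m`, so responder magnitudes track their driver.
  Defaults: `α_i ~ Uniform[0,1]` (seeded), driver assignment
  alternating (50/50 for 100 responders), `k_i = 1`.
* **Noise.** Each Euler step samples
  `g(t+Δt) ~ N(g + Δt·f(g), σ)` clamped at 0, with chemical-Langevin
  `σ_i = sqrt(Δt (synthesis_i + degradation_i)/s)`: birth and death
  events contribute independent Poisson-like variance, scaled by one
  knob `1/s` (default 0.05). The implied diffusion
  `Q_ii = (synthesis_i + degradation_i)/s` is the default noise
  covariance in Lyapunov solves (`noise_diffusion`).
* **Conditions.** 100 cells, `Δt = 0.01`, initial conditions uniform in
  `[0, 4]`, steady state read from the last timestep. Default
  `n_steps = 2×10⁴` (200 time units): the relaxation time is
  `~1/k_D = 1` time unit, so this is deep equilibration while staying
  desk-scale; longer runs are a config away and change nothing
  qualitatively. An optional equilibration check warns when the mean
  drift norm over the final 1% of steps stays large.

### Critical points of the driver core

`critical_control` exposes two indicators:

* `control="k_D"` (pitchfork): bisection on the sign of `λ_d` at the
  symmetric fixed point — the genuine loss of linear stability, giving
  `k_Dc = 0.5` at `m₁ = m₂ = 1`.
* `control="m1"` (saddle-node): the deterministic folds of the
  bistable strip (at `m₂ = 3`, `k_D = 1` they sit near `m₁ ≈ 2.70` and
  `≈ 3.55`) do **not** coincide with the point where the stochastic
  steady-state distribution is maximally bimodal. That point is the
  exchange-symmetric (balanced) value `m₁ = m₂`, where the middle
  saddle satisfies `g₁* = g₂*` exactly and the two basins are equally
  deep. We therefore bisect on the saddle asymmetry `g₁* − g₂*`,
  returning the balanced point (3 for `m₂ = 3`) — the value at which
  the covariance eigenvalue peaks in simulation. Outside the strip the
  unique fixed point carries the same asymmetry sign, so wide brackets
  are valid.

## Trajectory scan

* **Normalization.** "Cell-normalized" is read as unit row sum
  (total-count normalization); `median` and `none` are available. The
  simulated-network analyses use raw matrices (`none`), matching how
  the validation figures are computed; only the scRNA-seq-style
  pipeline normalizes.
* **Binning.** Cells sorted by pseudotime (stable ties), bins of
  `bin_size` starting every `step = round(bin_size (1 − overlap))`
  cells while a full bin fits; the final bin absorbs the tail
  (`bin_size ≤ size < bin_size + step`). Labels are 1-based. At
  trajectory scale (61,310 cells, 1000/50%) this yields 121 bins with
  a 1310-cell last bin.
* **Null.** Per bin and replicate, every gene column is permuted
  independently across cells — within-bin marginals are preserved
  exactly, all gene–gene correlation is destroyed. 20 replicates by
  default; z = (ω₁ − null mean)/null sd, computed on unshifted values.
  Min-shifting (for plots/tables) is applied separately to the data
  and null curves. This null is our reconstruction of the marginal
  resampling idea; the exact published construction was not available
  to us.
* **Classification.** A *one-to-one* spike is an isolated local
  maximum with `z ≥ 5` that returns below `z = 2` within 5 bins on
  both sides; a *one-to-many* onset is the first bin of a ≥10-bin run
  above `z = 2` with nonnegative trend; *step-like* (noise-induced
  switching) is a single change point between two low-slope plateaus
  at different levels. Thresholds are configurable; they are our
  choices, set so that planted saddle-node fixtures are detected and
  i.i.d. noise is not, and the report always carries raw z-scores so
  users can apply their own judgement.
* **DNB benchmark.** The composite index
  `I = SD_avg(DNB) · |PCC|_avg(within DNB) / (|PCC|_avg(DNB, rest) + ε)`
  (ε = 1e-6 guards the denominator) — the standard dynamical-network-
  biomarker order parameter. It requires choosing the candidate set;
  the eigenvalue signal does not, which is the point of the
  comparison.

## Eigenvector analytics

* Eigenvector correlation maps use raw Pearson correlation of loading
  profiles (absolute-loading mode available).
* Gene-set weights average **absolute** loadings (`W_c = mean |s_g|`
  over matched genes): a direction's mechanism is sign-symmetric. A
  signed mean is available. Genes absent from the matrix are ignored
  but counted.
* Projections are plain dot products of (optionally centred) cell rows
  with a unit direction; bimodality is declared when a two-component
  1-D Gaussian mixture beats one component by ΔBIC > 10 — a
  conservative, explicit criterion standing in for by-eye judgement.
* The two-component split is fitted in the bin's top-10 principal
  subspace with diagonal covariances (full-dimension diagonal fit by
  config): full-dimension covariances at 1000 cells × 25k genes are
  singular. For a one-to-many epoch use an eigenvector from the middle
  of its correlation block; for a one-to-one spike use the vector at
  the spike bin itself — a spike direction is only observable at the
  spike. Component "a" is the one with the smaller first-coordinate
  mean, making labels deterministic given the seed. The separation
  statistic is the Mahalanobis-style distance between component means
  under the pooled diagonal covariance.

## Fixture generator

`generate_fixture` emulates the *statistical* structure of a
bifurcating trajectory without dynamics: isotropic Gaussian noise
around a positive baseline plus a rank-1 component along a planted
random unit direction, whose per-cell standard deviation follows the
transition class (Gaussian bump of width `bin_size/4` for one-to-one;
linear ramp for one-to-many; level shift for step-like). It captures
exactly what the scan measures — a localized excess of directed
covariance — and deliberately omits real-data features: counts are
continuous not discrete, noise is homoscedastic, there is no
library-size variation, no gene-gene baseline correlation, and
pseudotime is exact rank. Passing tests on fixtures therefore
demonstrate correct *detection mechanics*, not robustness to scRNA-seq
artefacts; the stochastic network covers nonlinearity and realistic
noise coupling, and real-data idiosyncrasies (ambient RNA, doublets,
pseudotime error) remain out of scope.

## Problem sizes and determinism

Simulation-based checks run at 100 cells × 102 genes × 2×10⁴ steps
(the sweep, ~8 s per grid point); detection calibration uses 20 runs
each of 2000 cells × 40 genes. All randomness flows from explicit
seeds through `numpy.random.default_rng`; sweep members derive their
seeds from the base seed and grid index, so every pipeline is
reproducible end to end and outputs are byte-stable.

## Known limitations

* The artifact consumes pseudotime; it does not infer it. Pseudotime
  error blurs bins and weakens spikes.
* One-to-many onsets are intrinsically harder to separate from the
  null than one-to-one spikes (the signal grows from zero); onset
  localization is ±3 bins on clean fixtures.
* The m1-balance indicator assumes the exchange symmetry of the
  two-driver core; for asymmetric generalizations the fold values
  themselves (λ_d indicator on a tracked stable branch) are the
  meaningful critical parameters.
* The Lyapunov default `Q` is diagonal; correlated noise is not
  estimated from data.
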