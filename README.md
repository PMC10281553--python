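# bifurscan

Detecting and characterizing bifurcations in high-dimensional
expression trajectories from the eigendecomposition of gene–gene
covariance.

## The problem

Cell-fate transitions are often pictured as bifurcations of an
underlying dynamical system: a stable transcriptomic state loses
stability and jumps (maturation, a one-to-one transition) or splits
(a decision, one-to-many). Single-cell RNA-seq measures thousands of
genes across many cells ordered in pseudotime, but gives no access to
the governing equations. `bifurscan` asks a question that can be
answered from the data alone: *does a pseudotime trajectory carry the
statistical signatures a bifurcation must leave in the covariance?*

If cells near one pseudotime are statistical replicates fluctuating
around a fixed point `g*` of dynamics with Jacobian `J`, stationarity
implies the continuous-time Lyapunov equation for the gene–gene
covariance `C`:

```
J C + C Jᵀ + Q = 0
```

As the largest Jacobian eigenvalue `λ_d → 0⁻` (the defining approach to
a bifurcation), three observable consequences follow:

* `ω₁`, the largest eigenvalue of `C`, diverges;
* `ŝ₁`, the principal covariance eigenvector, converges (up to sign) to
  the Jacobian's slow eigenvector — the *direction* of the bifurcation
  in gene space;
* pairwise Pearson correlations with loadings on that direction expand
  toward ±1.

The package implements this scan — bin cells along pseudotime, track
`ω₁(τ)` against a gene-shuffling null, classify spikes (one-to-one)
versus sustained increases (one-to-many) versus plateaus-with-a-step
(noise-induced switching), and analyze the eigenvectors at detected
transitions — plus the stochastic two-driver gene-regulatory network
used to validate every step, a dynamical-network-biomarker (DNB)
benchmark, Gaussian-mixture splitting of coexisting modes, and
gene-set (GMT) scoring of eigenvector loadings. It is aimed at
computational biologists who already have a pseudotime-ordered
cells × genes matrix; pseudotime inference itself is out of scope.

## Worked example

Generate a synthetic trajectory with a planted one-to-one transition at
bin 15 and scan it:

```python
from bifurscan import FixtureSpec, generate_fixture, scan

fx = generate_fixture(FixtureSpec(
    n_cells=3000, n_genes=60, bin_size=200,
    transition_bin=15, transition_class="one-to-one",
    effect_size=10.0, seed=5,
))
traj, report = scan(fx.matrix, bin_size=200, overlap=0.5,
                    normalization="none", seed=5)
print(traj.to_frame().loc[12:17, ["bin", "omega1", "null_mean", "null_sd", "z"]])
print(report.to_dict())
```

```
 bin  omega1  null_mean  null_sd       z
  13   2.384      2.360    0.086   0.279
  14  20.729      3.850    0.173  97.622
  15  38.964      5.903    0.159 207.582
  16  19.365      3.755    0.086 181.556
  17   2.399      2.352    0.095   0.489

{'classification': 'one-to-one',
 'events': [{'bin': 15, 'kind': 'one-to-one', 'z': 207.58, 'window': [15, 17]}]}
```

Away from the transition, `ω₁` is indistinguishable from the
permutation null (z ≈ 0): the covariance carries no directed structure
beyond what independent genes produce. At bin 15 the planted state jump
concentrates variance along one direction and `ω₁` spikes two hundred
null standard deviations above chance; the spike returns to baseline
within two bins, so it is classified as a one-to-one transition at
exactly the planted bin. The principal eigenvector at the spike bin
recovers the planted direction (sign-invariant Euclidean distance
< 0.2), which is how, on real data, the gene loadings at a detected
transition identify the genes driving it.

The same machinery runs from the shell:

```
bifurscan simulate --n-genes 102 --n-cells 100 --m1 3 --m2 3 --kd 1 \
    --noise 0.05 --steps 20000 --seed 1 --out matrix.tsv
bifurscan scan --matrix matrix.tsv --bin-size 40 --normalization none \
    --seed 1 --out scan.tsv --report report.json
bifurscan critical --m1 1 --m2 1 --control kd --bracket 0.24 5
```

## The validation network

`grn_sim` implements two mutually inhibiting driver genes (a toggle
switch, Hill coefficient 2) plus 100 responders coupled to one driver
each with strength `α_i ∈ [0, 1]`, integrated with Gaussian
chemical-Langevin noise. Its bifurcation structure is known exactly —
a pitchfork at `k_D = 0.5` for `m1 = m2 = 1` and a saddle-node
structure in `m1` with balanced bimodality at `m1 = m2` — so every
covariance-level claim can be checked against analytic ground truth:
the Lyapunov-predicted covariance matches long simulations, `ω₁` peaks
at the critical `m1`, the principal covariance eigenvector converges
to the slow Jacobian eigenvector, and correlation distributions expand
at the bifurcation. See `docs/methods.md` for model details and all
numerical choices.

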