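# Methods

This note documents the statistical model behind the package, the
numerical choices made where the design was genuinely open, what the
synthetic benchmark does and does not emulate, and known limitations.

## Model and estimator

The data `x_1..x_n ⊂ R^D` are modelled, locally around each point, as a
realisation of a spatial Poisson process with intensity constant on a
ball `B(x_i, r_B)`. Two standard consequences are used:

1. With `r_A = τ·r_B` (`0 < τ < 1`), the inner-ball counts are
   conditionally binomial, `k_A | k_B ~ Binomial(k_B, τ^d)`, giving the
   closed-form MLE `d̂ = log(Σk_A / Σk_B)/log τ` (the binomial
   intrinsic-dimension estimate, BIDE).
2. The volumes of the hyper-spherical shells between consecutive
   neighbour radii, `v_{i,j} = Ω_d (r_{i,j}^d − r_{i,j−1}^d)` with
   `Ω_d = π^{d/2}/Γ(d/2+1)`, are i.i.d. `Exponential(ρ_i)` while
   homogeneity holds, so the log-likelihood of the first `k` shells is
   `L_{i,k}(ρ) = k log ρ − ρ V_{i,k}` with `V_{i,k} = Ω_d r_{i,k}^d`
   (telescoping).

The homogeneity test at neighbourhood order `k` compares the intensity at
`x_i` (its first `k` shells) with the intensity at the `(k+1)`-th nearest
neighbour of `x_i`, measured over that neighbour's *own* first `k`
shells. Profiling both likelihoods yields the closed form
`D_{i,k} = 2k log[(V + V′)²/(4 V V′)]`, which is χ²₁ under the null; the
per-point neighbourhood size is the first `k` that rejects,
`k*_i = min{k : D_{i,k} ≥ q_{1−α,1}}`, taken literally as the first
rejecting order. Points that never reject keep `k* = k_max` and are
flagged `capped`. Because the cumulative volumes telescope, `Ω_d`
cancels and `D_{i,k}` depends on `d` only through the radius ratio
`(r/r′)^d`, which keeps the scan cheap and numerically safe (the ratio is
computed on the smaller/larger ordering, so no overflow at large `d`).

ABIDE alternates (scan at current `d`) → (counts from the selected
neighbourhoods) → (BIDE update) until `|Δd̂| ≤ tol`. The iteration map is
a step function of `d`, so convergence is typically exact after two or
three rounds.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `τ` | 0.5 | balanced inner/outer counts; `p = τ^d` stays resolvable for `d ≲ 15` |
| `α` | 0.01 | conservative rejection → larger, smoother neighbourhoods |
| `k_min` | 3 | the LRT at `k < 3` is dominated by shell noise |
| `k_max` | `min(n−1, 100)` | caps the scan cost; wide enough for all fitted benchmarks |
| `init_k` | 10 | one-shot BIDE at fixed `k = 10` seeds the iteration |
| `tol` | 1e−3 | below the step granularity of the iteration map |
| `max_iter` | 50 | oscillations are rare; on hitting the cap the average of the last two iterates is returned with `converged_ = False` |

All are configurable; every fitted estimator records them.

Degenerate inputs: shells of zero volume (duplicate points) carry no
likelihood information, so the scan treats their statistic as 0 and
effectively merges duplicates forward; points whose entire neighbourhood
is coincident are excluded from the binomial totals with a warning.
Boundary counts use a closed inner ball (`≤ τ·r_B`).

The reported standard deviation is a delta-method approximation that
treats the pooled inner count as a single binomial draw,
`sqrt((1−p)/(p·Σk_B·log²τ))` with `p = τ^{d̂}`. It ignores inter-point
dependence and is indicative only. `d*` is `d̂` rounded half away from
zero; both values are always exposed.

## Adaptive embedders

**LLE.** Reconstruction weights solve the sum-to-one constrained least
squares through the local Gram system. When the Gram matrix is singular
(which includes every neighbourhood with `k > D`) a ridge
`reg·trace(G)/k`, `reg = 1e−3`, conditions it. scikit-learn's solver uses
`reg·trace(G)` without the `1/k`; passing `reg = k·1e−3` reproduces it
exactly, which is how the degeneration test pins the fixed-k path to the
classical implementation. The embedding takes the bottom eigenvectors of
`(I−W)ᵀ(I−W)` (dense below 500 points, shift-invert ARPACK above, dense
fallback). Because the trivial constant mode can be numerically
degenerate with the smallest informative modes, the constant direction is
projected out of the whole bottom block and the result re-orthonormalised
— this enforces `Σy_i = 0` and `(1/n)YᵀY = I` to machine precision rather
than solver precision. Reported cost is `n` times the retained
eigenvalue sum. Disconnected weight graphs embed the largest weakly
connected component; remaining rows are NaN with a warning.

Out-of-sample projection re-runs the `k*` scan for the test point at the
trained `d̂` (training `τ`, `α`, `k` range), solves its reconstruction
weights on its `k*` training neighbours, and maps it to the weighted
combination of their embeddings. The training graph is never modified.

**Spectral.** Union-symmetrized binary `k*` graph, symmetric normalised
Laplacian, eigenvectors of the `d*` smallest non-trivial eigenvalues,
K-means with 10 restarts on the raw eigenvector rows (row-normalisation
is a flag). If the graph is disconnected, components are joined greedily
by their shortest inter-component edge (each addition logged) because the
spectral embedding of a disconnected graph mixes component indicators.

**UMAP.** The fuzzy calibration keeps standard UMAP's defining equation
but with per-point targets `log₂ k*_i`. The width search itself — binary
search to `|Σ − target| < 1e−5`, ≤ 64 halvings, widths floored at `1e−3`
of the mean neighbour distance — is delegated to umap-learn's
`smooth_knn_dist`, called once per distinct `k*` value; this makes the
fixed-`k*` degeneration bit-identical to a standard UMAP graph, whereas an
independent float64 re-implementation differs by ~1e−6 in weight space
purely through the float32 early-stopping of the reference search.
Membership weights are evaluated in float32 for the same reason. Points
with `k* = 1` have an unattainable target (`log₂ 1 = 0` but the nearest
non-coincident neighbour always contributes weight 1); their width
collapses to the floor and a warning is raised. Symmetrization uses the
probabilistic t-conorm computed as `1 − (1−w)(1−w′)` so that a weight of
exactly 1 stays exactly 1. The layout stage minimises the usual fuzzy
cross-entropy with `a, b` fitted from `min_dist = 0.1`, `spread = 1.0`,
negative-sampling rate 5, spectral initialisation; it can run through
umap-learn (`layout="reference"`, default) or the built-in numba SGD
(`layout="builtin"`), both deterministic given `random_state`.

## Synthetic benchmark

`generate_manifold_dataset` mixes 1700 points each from a torus
(`R = 2`, `r = 0.5`, area-uniform via rejection on the poloidal angle), a
conical spiral (`0.25·(t cos t, t sin t, t)`, `t ∈ [0, 4π]`, offset to
`z + 1.5`) and a unit sphere, adds `N(0, 0.1²)` noise to the three
manifold coordinates and pads with 17 pure `N(0, 0.02²)` coordinates to
`D = 20`. The 3-D noise thickens the 2-D surfaces into locally
3-dimensional clouds, so the designed de-noised intrinsic dimension is 3;
the two noise scales were chosen once so that the manifold thickening is
resolved at the neighbourhood scale while the padding noise is not
(`d* = 3` holds across seeds; `0.05/0.05` instead pushes `d̂` toward 8
because the padding noise becomes comparable to the neighbour spacing).
The sphere sits inside the torus hole (surface gap 0.5) and the spiral
is adjacent above, keeping the neighbourhood graph connected and the
clustering task non-trivial.

What the generator does *not* emulate: real datasets' anisotropic and
heavy-tailed noise, feature correlations, uneven class sizes, and the
exact geometry of any deposited benchmark file — so passing tests here
demonstrates correct mechanics and parameter recovery under the stated
model, not performance claims on any external dataset. Uniform
hypercube and hypersphere-surface samplers provide exact-dimension
fixtures for recovery tests (`d ∈ {2, 3, 5}`, `n = 2000` — large enough
for reliable integer recovery, small enough to keep the suite fast).

## Evaluation harness

K-means (10 restarts, seeded) with as many clusters as ground-truth
labels, scored by ARI, homogeneity, completeness and V-measure (harmonic
mean of the latter two); fixed-k grid-search baselines over the three
non-adaptive pipelines with per-cell failure capture; and a supervised
probe — stratified 3-fold cross-validation of an unpenalised multinomial
logistic regression trained on the fitted embedding and applied to
out-of-sample projections, reporting accuracy and macro-F1 (classes are
near-balanced in all bundled benchmarks).

## Known limitations

* The χ²₁ calibration of `D_{i,k}` is asymptotic; at `k_min = 3` the
  finite-sample level differs from `α`, which slightly biases `k*`
  downward in very sparse regions.
* The delta-method standard deviation underestimates uncertainty because
  neighbouring counts are strongly dependent.
* `τ^d` underflows the usable counting range for `d ≳ 20` at `τ = 0.5`;
  very high-dimensional data need a larger `τ`.
* Exact nearest neighbours cost `O(n²)` memory in the current
  implementation; approximate search is deliberately excluded because
  the likelihood is built on exact ordered radii.
* The out-of-sample rule assumes the test point lies on the trained
  manifold; far-away queries silently extrapolate through their nearest
  training neighbours.
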