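# adaptive-manifold

Neighbourhood-based dimensionality reduction — locally linear embedding
(LLE), spectral embedding, UMAP — requires two hyper-parameters that
practitioners usually guess: the number of nearest neighbours `k` and the
target dimension of the projection. This package estimates both from the
data, jointly, and feeds them into adaptive versions of all three
embedders. It is aimed at anyone embedding high-dimensional tabular,
image or text-embedding matrices (e.g. omics feature tables or SBERT
vectors) who would rather not grid-search `n_neighbors` × `n_components`.

## The model

Assume the sample `x_1..x_n ⊂ R^D` lies near a `d`-dimensional manifold
(`d < D`) and is locally a realisation of a homogeneous Poisson process.
Two consequences drive everything here:

**Binomial intrinsic-dimension estimate (BIDE).** For concentric balls of
radii `r_A = τ·r_B` around each point, the inner counts satisfy
`k_A | k_B ~ Binomial(k_B, τ^d)`, and the maximum-likelihood dimension is

    d̂ = log(Σᵢ k_{A,i} / Σᵢ k_{B,i}) / log τ .

**Adaptive neighbourhood selection.** Under local homogeneity the
hyper-spherical shell volumes `v_{i,j} = Ω_d (r_{i,j}^d − r_{i,j−1}^d)`
between consecutive neighbour radii are i.i.d. exponential. Scanning
`k = k_min, k_min+1, …`, a likelihood-ratio statistic

    D_{i,k} = 2k · log( (V_{i,k} + V'_{k})² / (4 V_{i,k} V'_{k}) )

compares the shell intensity at `x_i` with that at its `(k+1)`-th
neighbour; the neighbourhood stops growing at the first `k` whose `D_{i,k}`
exceeds the `(1−α)` quantile of χ²₁:

    k*_i = min{ k : D_{i,k} ≥ q_{1−α,1} } .

The **ABIDE** estimator iterates the scan and the binomial estimate until
`d̂` stabilises, returning `d̂`, its integer rounding `d*`, a delta-method
standard deviation, and the per-point sizes `k*_{1:n}`.

The adaptive embedders then replace the global `k` with `k*_{1:n}` and the
projection dimension with `d*`:

* `AdaptiveLLE` — barycentric reconstruction weights on each point's own
  `k*_i` neighbours, embedding from the bottom eigenvectors of
  `(I−W)ᵀ(I−W)` under the centering and unit-covariance constraints, plus
  an out-of-sample projection (`transform`) that re-runs the `k*` scan for
  each new point.
* `AdaptiveSpectralClustering` — normalised-Laplacian embedding of the
  union-symmetrized `k*` graph, then K-means.
* `AdaptiveUMAP` — per-point fuzzy calibration
  `Σⱼ exp(−max(0, d_ij − ρ_i)/σ_i) = log₂ k*_i`, t-conorm symmetrization,
  and the usual cross-entropy layout (delegated to umap-learn or run by
  the built-in optimizer, `layout="builtin"`).

All estimators follow scikit-learn conventions (`fit`, `fit_transform`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn pipelines and model selection.

## Worked example

The bundled generator reproduces a benchmark of three noisy 3-D manifolds
(a torus, a conical spiral and a sphere; 5100 points, padded with noise
coordinates to D = 20), whose de-noised intrinsic dimension is 3 by
construction:

```python
import numpy as np
from adaptive_manifold import (
    ABIDE, AdaptiveUMAP, generate_manifold_dataset, kmeans_evaluate,
)
from adaptive_manifold.synth import ManifoldSpec

X, labels, _ = generate_manifold_dataset(ManifoldSpec(seed=0))
est = ABIDE().fit(X)
print(f"d_hat = {est.d_hat_:.2f} +/- {est.std_:.2f}, d* = {est.d_star_}, "
      f"k* median = {np.median(est.k_star_):.0f} "
      f"(range {est.k_star_.min()}-{est.k_star_.max()})")

model = AdaptiveUMAP(n_components=2, random_state=0).fit(X)
rep = kmeans_evaluate(model.embedding_, labels, seed=0)
print(f"UMAP* ARI = {rep.ari:.3f}, V-measure = {rep.v_measure:.3f}")
```

prints

```
d_hat = 2.97 +/- 0.01, d* = 3, k* median = 36 (range 4-100)
UMAP* ARI = 0.641, V-measure = 0.663
```

The dimension estimate recovers the designed value (`d* = 3`) and the
wide spread of `k*` reflects the strongly varying sampling density across
the three shapes — exactly the regime where a single global `k` is a bad
compromise. The ARI scores the K-means clustering of the 2-D embedding
against the true shape labels. On the 150×4 Iris table the same estimator
gives `d_hat = 2.69 +/- 0.07`.

A thin CLI mirrors the library (`adaptive-manifold fit-id`, `embed
{lle,spectral,umap}`, `project`, `synth`, `evaluate`, `benchmark`); all
I/O is delimited text and JSON.

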