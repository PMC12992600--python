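"""Adaptive UMAP.

Standard UMAP calibrates, for every point, a local kernel width
``sigma_i`` so that the total fuzzy membership of its ``k`` nearest
neighbours equals ``log2(k)`` for one global ``k``.  The adaptive variant
keeps the whole construction but lets each point use its own
neighbourhood size ``k*_i`` from the dimension estimator, calibrating

    sum_{j in N(i)} exp(-max(0, d_ij - rho_i) / sigma_i) = log2(k*_i),

with ``rho_i`` the distance to the first non-coincident neighbour.  The
resulting directed membership weights are symmetrized with the
probabilistic t-conorm ``w + w' - w w'`` and the low-dimensional layout
minimises the usual fuzzy-set cross-entropy, in ``d*`` dimensions unless
overridden.

Two layout engines are available: ``layout="reference"`` hands the
symmetrized graph to umap-learn's optimizer, ``layout="builtin"`` runs the
negative-sampling SGD implemented here.  Both are deterministic given
``random_state``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numba
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.utils import check_random_state

from .graphs import adaptive_adjacency, symmetrize
from .idestimate import ABIDE
from .neighbors import NeighborTable, _validate_matrix

__all__ = [
    "FuzzyCalibration",
    "smooth_knn_calibration",
    "fuzzy_graph",
    "AdaptiveUMAP",
]

@dataclass(frozen=True)
class FuzzyCalibration:
    """Per-point fuzzy kernel calibration.

    ``conn_offset`` is the connectivity offset (distance to the first
    non-coincident neighbour — UMAP's ``rho``, renamed to avoid clashing
    with the Poisson intensity of the dimension estimator); ``sigma`` the
    calibrated kernel widths; ``target`` the attained membership targets
    ``log2(k*_i)``.
    """

    conn_offset: np.ndarray
    sigma: np.ndarray
    target: np.ndarray


def _smooth_knn_batch(dist_rows: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-width search for a batch of points sharing one target.

    Delegates the bisection itself to the reference UMAP routine (binary
    search to ``|sum - log2(k)| < 1e-5`` in at most 64 halvings, widths
    floored at 1e-3 of the mean neighbour distance), which keeps the
    fixed-k degeneration bit-identical to a standard UMAP graph.  The
    routine expects the self-distance (zero) in the first column.
    """
    from umap.umap_ import smooth_knn_dist

    padded = np.hstack(
        [np.zeros((dist_rows.shape[0], 1), dtype=np.float32), dist_rows]
    ).astype(np.float32)
    sigma, rho = smooth_knn_dist(padded, float(k))
    return np.asarray(sigma, dtype=float), np.asarray(rho, dtype=float)


def _calibrate_row(dists: np.ndarray, target_k: float) -> tuple[float, float]:
    """Calibrate a single point against the target ``log2(target_k)``."""
    dists = np.asarray(dists, dtype=np.float32)[None, :]
    sigma, rho = _smooth_knn_batch(dists, target_k)
    return float(sigma[0]), float(rho[0])


def smooth_knn_calibration(
    table: NeighborTable, neighborhood
) -> FuzzyCalibration:
    """Calibrate per-point kernel widths to membership targets ``log2(k*_i)``.

    Points with ``k* = 1`` have an unattainable target (the first
    neighbour always contributes weight 1, while ``log2(1) = 0``); their
    width collapses to the floor and a warning is emitted.
    """
    k_star = (
        neighborhood.k_star if hasattr(neighborhood, "k_star") else np.asarray(neighborhood)
    )
    n = table.n
    if k_star.shape != (n,):
        raise ValueError("k_star length must match the table")
    target = np.log2(k_star.astype(float))
    if (k_star == 1).any():
        warnings.warn(
            "points with k* = 1 have target log2(1) = 0; their kernel "
            "width is set to the floor"
        )
    sigma = np.empty(n)
    rho = np.empty(n)
    # one search per distinct k*: points in a group share the target
    for kv in np.unique(k_star):
        idx = np.flatnonzero(k_star == kv)
        s, r = _smooth_knn_batch(
            table.distances[idx, :kv].astype(np.float32), int(kv)
        )
        sigma[idx] = s
        rho[idx] = r
    return FuzzyCalibration(conn_offset=rho, sigma=sigma, target=target)


def fuzzy_graph(
    table: NeighborTable, neighborhood, calibration: FuzzyCalibration
) -> sp.csr_matrix:
    """Symmetrized fuzzy membership graph on the adaptive adjacency support.

    Directed weights ``exp(-max(0, d - rho_i) / sigma_i)`` followed by the
    probabilistic t-conorm symmetrization ``W + W' - W o W'``.
    """
    A = adaptive_adjacency(table, neighborhood)
    k_star = (
        neighborhood.k_star if hasattr(neighborhood, "k_star") else np.asarray(neighborhood)
    )
    n = table.n
    data = np.empty_like(A.data)
    # float32 kernel evaluation, matching the calibration arithmetic
    for i in range(n):
        sl = slice(A.indptr[i], A.indptr[i + 1])
        d = table.distances[i, : k_star[i]].astype(np.float32)
        shifted = d - np.float32(calibration.conn_offset[i])
        sig = np.float32(calibration.sigma[i])
        data[sl] = np.where(
            shifted > 0, np.exp(-(shifted / sig), dtype=np.float32), np.float32(1.0)
        )
    W = sp.csr_matrix((data, A.indices.copy(), A.indptr.copy()), shape=(n, n))
    return symmetrize(W, "fuzzy_union")


# ---------------------------------------------------------------------------
# built-in cross-entropy layout (negative-sampling SGD)


@numba.njit(cache=True)
def _clip(x):
    if x > 4.0:
        return 4.0
    if x < -4.0:
        return -4.0
    return x


@numba.njit(cache=True)
def _xorshift(state):
    state ^= state << 13
    state &= 0xFFFFFFFFFFFFFFFF
    state ^= state >> 7
    state ^= state << 17
    state &= 0xFFFFFFFFFFFFFFFF
    return state


@numba.njit(cache=True)
def _sgd_layout(
    emb,
    head,
    tail,
    epochs_per_sample,
    a,
    b,
    gamma,
    initial_alpha,
    negative_sample_rate,
    n_epochs,
    seed,
):
    n, dim = emb.shape
    n_edges = head.shape[0]
    epoch_of_next = epochs_per_sample.copy()
    eps_neg = epochs_per_sample / negative_sample_rate
    epoch_of_next_neg = eps_neg.copy()
    state = np.uint64(seed * 2654435761 + 1)
    for epoch in range(n_epochs):
        alpha = initial_alpha * (1.0 - epoch / n_epochs)
        for e in range(n_edges):
            if epoch_of_next[e] > epoch:
                continue
            i = head[e]
            j = tail[e]
            d2 = 0.0
            for c in range(dim):
                diff = emb[i, c] - emb[j, c]
                d2 += diff * diff
            if d2 > 0.0:
                coef = (-2.0 * a * b * d2 ** (b - 1.0)) / (1.0 + a * d2**b)
            else:
                coef = 0.0
            for c in range(dim):
                g = _clip(coef * (emb[i, c] - emb[j, c]))
                emb[i, c] += alpha * g
                emb[j, c] -= alpha * g
            epoch_of_next[e] += epochs_per_sample[e]
            n_neg = int((epoch - epoch_of_next_neg[e] + eps_neg[e]) / eps_neg[e])
            for _ in range(n_neg):
                state = _xorshift(state)
                j2 = int(state % np.uint64(n))
                if j2 == i:
                    continue
                d2 = 0.0
                for c in range(dim):
                    diff = emb[i, c] - emb[j2, c]
                    d2 += diff * diff
                if d2 > 0.0:
                    coef = (2.0 * gamma * b) / ((0.001 + d2) * (1.0 + a * d2**b))
                else:
                    coef = 0.0
                for c in range(dim):
                    if coef > 0.0:
                        g = _clip(coef * (emb[i, c] - emb[j2, c]))
                    else:
                        g = 4.0
                    emb[i, c] += alpha * g
            epoch_of_next_neg[e] += n_neg * eps_neg[e]
    return emb


def _find_ab(spread: float, min_dist: float) -> tuple[float, float]:
    from umap.umap_ import find_ab_params

    return find_ab_params(spread, min_dist)


def _spectral_init(graph: sp.csr_matrix, dim: int, rng) -> np.ndarray:
    from scipy.sparse.csgraph import connected_components

    n = graph.shape[0]
    if connected_components(graph, directed=False)[0] > 1:
        return rng.uniform(-10.0, 10.0, size=(n, dim))
    from .spectral import spectral_embed

    try:
        Y = spectral_embed(graph, dim)
    except Exception:
        return rng.uniform(-10.0, 10.0, size=(n, dim))
    expansion = 10.0 / np.abs(Y).max()
    return Y * expansion + rng.normal(scale=1e-4, size=Y.shape)


def _builtin_layout(
    graph: sp.csr_matrix,
    n_components: int,
    n_epochs: int,
    a: float,
    b: float,
    gamma: float,
    initial_alpha: float,
    negative_sample_rate: int,
    random_state: int,
) -> np.ndarray:
    graph = sp.coo_matrix(graph)
    w = graph.data.copy()
    w[w < w.max() / float(n_epochs)] = 0.0  # prune edges sampled less than once
    keep = w > 0
    head = graph.row[keep].astype(np.int64)
    tail = graph.col[keep].astype(np.int64)
    w = w[keep]
    epochs_per_sample = w.max() / w
    rng = np.random.default_rng(random_state)
    emb = np.ascontiguousarray(
        _spectral_init(sp.csr_matrix(graph), n_components, rng), dtype=np.float64
    )
    return _sgd_layout(
        emb,
        head,
        tail,
        epochs_per_sample,
        a,
        b,
        gamma,
        initial_alpha,
        negative_sample_rate,
        n_epochs,
        random_state,
    )


def _reference_layout(
    X: np.ndarray,
    graph: sp.csr_matrix,
    n_components: int,
    n_epochs: int,
    a: float,
    b: float,
    gamma: float,
    initial_alpha: float,
    negative_sample_rate: int,
    random_state: int,
) -> np.ndarray:
    from umap.umap_ import simplicial_set_embedding

    result = simplicial_set_embedding(
        data=X.astype(np.float32),
        graph=graph.tocoo(),
        n_components=n_components,
        initial_alpha=initial_alpha,
        a=a,
        b=b,
        gamma=gamma,
        negative_sample_rate=negative_sample_rate,
        n_epochs=int(n_epochs),
        init="spectral",
        random_state=check_random_state(random_state),
        metric="euclidean",
        metric_kwds={},
        densmap=False,
        densmap_kwds={},
        output_dens=False,
        parallel=False,
        verbose=False,
    )
    emb = result[0] if isinstance(result, tuple) else result
    return np.asarray(emb, dtype=float)


class AdaptiveUMAP(BaseEstimator):
    """UMAP with per-point neighbourhood sizes and data-driven dimension.

    Parameters
    ----------
    n_components : int, optional
        Embedding dimension; defaults to ``d*``.
    k_fixed : int, optional
        Force a constant neighbourhood size (degeneration to standard
        UMAP's graph); requires ``n_components``.
    layout : {"reference", "builtin"}, default "reference"
        Cross-entropy optimizer: delegate to umap-learn or use the SGD
        implemented in this module.
    n_epochs : int, default 500
    min_dist, spread : floats, default 0.1 / 1.0
        Shape of the low-dimensional kernel (the usual a, b fit).
    negative_sample_rate : int, default 5
    repulsion_strength : float, default 1.0
    random_state : int, default 0
    tau, alpha, k_min, k_max, init_k, tol, max_iter
        Forwarded to :class:`~adaptive_manifold.idestimate.ABIDE`.

    Attributes
    ----------
    embedding_ : (n, n_components_) array
    graph_ : symmetrized fuzzy membership graph
    calibration_ : FuzzyCalibration
    abide_ : fitted ABIDE instance (absent with ``k_fixed``)
    """

    def __init__(
        self,
        n_components: int | None = None,
        k_fixed: int | None = None,
        layout: str = "reference",
        n_epochs: int = 500,
        min_dist: float = 0.1,
        spread: float = 1.0,
        negative_sample_rate: int = 5,
        repulsion_strength: float = 1.0,
        learning_rate: float = 1.0,
        random_state: int = 0,
        tau: float = 0.5,
        alpha: float = 0.01,
        k_min: int = 3,
        k_max: int = 100,
        init_k: int = 10,
        tol: float = 1e-3,
        max_iter: int = 50,
    ):
        self.n_components = n_components
        self.k_fixed = k_fixed
        self.layout = layout
        self.n_epochs = n_epochs
        self.min_dist = min_dist
        self.spread = spread
        self.negative_sample_rate = negative_sample_rate
        self.repulsion_strength = repulsion_strength
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.tau = tau
        self.alpha = alpha
        self.k_min = k_min
        self.k_max = k_max
        self.init_k = init_k
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        if self.layout not in ("reference", "builtin"):
            raise ValueError("layout must be 'reference' or 'builtin'")
        X = _validate_matrix(X)
        n = X.shape[0]
        if self.k_fixed is not None and self.n_components is not None:
            from .neighbors import build_neighbor_table

            table = build_neighbor_table(X, min(max(self.k_fixed, 1), n - 1))
            k_star = np.full(n, self.k_fixed, dtype=np.int64)
        else:
            est = ABIDE(
                tau=self.tau,
                alpha=self.alpha,
                k_min=self.k_min,
                k_max=self.k_max,
                init_k=self.init_k,
                tol=self.tol,
                max_iter=self.max_iter,
            ).fit(X)
            self.abide_ = est
            table = est.neighbor_table_
            k_star = (
                np.full(n, self.k_fixed, dtype=np.int64)
                if self.k_fixed is not None
                else est.k_star_
            )
            self.d_star_ = est.d_star_
        self.k_star_ = k_star
        self.n_components_ = (
            self.n_components
            if self.n_components is not None
            else max(self.abide_.d_star_, 2)
        )
        self.calibration_ = smooth_knn_calibration(table, k_star)
        self.graph_ = fuzzy_graph(table, k_star, self.calibration_)
        a, b = _find_ab(self.spread, self.min_dist)
        self._ab_ = (a, b)
        if self.layout == "reference":
            self.embedding_ = _reference_layout(
                X,
                self.graph_,
                self.n_components_,
                self.n_epochs,
                a,
                b,
                self.repulsion_strength,
                self.learning_rate,
                self.negative_sample_rate,
                self.random_state,
            )
        else:
            self.embedding_ = _builtin_layout(
                self.graph_,
                self.n_components_,
                self.n_epochs,
                a,
                b,
                self.repulsion_strength,
                self.learning_rate,
                self.negative_sample_rate,
                self.random_state,
            )
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def umap_star_fit(X, **params):
    """Functional wrapper returning (embedding, fitted estimator)."""
    model = AdaptiveUMAP(**params).fit(X)
    return model.embedding_, model
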