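"""Adaptive spectral embedding and clustering.

The adaptive adjacency (each point linked to its ``k*_i`` nearest
neighbours, union-symmetrized) replaces the fixed-k similarity graph of
standard spectral clustering; the embedding dimension defaults to the
rounded intrinsic-dimension estimate ``d*``.  The embedding itself is the
classical one: eigenvectors of the ``d_proj`` smallest non-trivial
eigenvalues of the symmetric normalised Laplacian
``L = I - D^{-1/2} A D^{-1/2}``, followed by K-means.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components, laplacian
from scipy.sparse.linalg import ArpackError, eigsh
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances
from sklearn.utils.validation import check_is_fitted

from .graphs import adaptive_adjacency, symmetrize
from .idestimate import ABIDE
from .neighbors import _validate_matrix

__all__ = ["spectral_embed", "AdaptiveSpectralClustering", "sc_star", "repair_connectivity"]


def spectral_embed(
    A: sp.spmatrix,
    d_proj: int,
    row_normalize: bool = False,
    dense_threshold: int = 500,
) -> np.ndarray:
    """Laplacian eigenmap coordinates from a symmetric affinity graph.

    Uses the symmetric normalised Laplacian and returns the eigenvectors
    belonging to the ``d_proj`` smallest eigenvalues after the trivial
    one.  Raises on isolated vertices (their normalised degree is
    undefined) — repair connectivity first.
    """
    A = sp.csr_matrix(A)
    n = A.shape[0]
    if d_proj < 1 or d_proj > n - 2:
        raise ValueError("d_proj out of range")
    if (abs(A - A.T) > 1e-12 * max(1.0, abs(A).max())).nnz:
        raise ValueError("affinity matrix must be symmetric")
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = np.flatnonzero(deg == 0)
    if isolated.size:
        raise ValueError(f"isolated vertices in the graph: {isolated[:10].tolist()}")
    L = laplacian(A, normed=True)
    k = d_proj + 1
    if n < dense_threshold:
        vals, vecs = eigh(L.toarray(), subset_by_index=(0, k - 1))
    else:
        try:
            vals, vecs = eigsh(L.tocsc(), k=k, sigma=0.0, which="LM")
        except (ArpackError, RuntimeError):
            vals, vecs = eigh(L.toarray(), subset_by_index=(0, k - 1))
    order = np.argsort(vals)
    Y = vecs[:, order[1 : d_proj + 1]]
    if row_normalize:
        norms = np.linalg.norm(Y, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        Y = Y / norms
    return Y


def repair_connectivity(A: sp.spmatrix, X: np.ndarray) -> sp.csr_matrix:
    """Join disconnected graph components by their shortest inter-component edge.

    Components are merged greedily (closest pair first, by Euclidean
    distance in the ambient space); each added edge is symmetric with
    weight 1 and is logged through ``warnings``.
    """
    A = sp.csr_matrix(A).tolil()
    n_comp, labels = connected_components(A.tocsr(), directed=False)
    while n_comp > 1:
        best = None
        for a in range(n_comp):
            ia = np.flatnonzero(labels == a)
            for b in range(a + 1, n_comp):
                ib = np.flatnonzero(labels == b)
                D = pairwise_distances(X[ia], X[ib])
                pos = np.unravel_index(D.argmin(), D.shape)
                cand = (D[pos], ia[pos[0]], ib[pos[1]])
                if best is None or cand[0] < best[0]:
                    best = cand
        _, i, j = best
        warnings.warn(f"connectivity repair: adding edge ({i}, {j})")
        A[i, j] = 1.0
        A[j, i] = 1.0
        n_comp, labels = connected_components(A.tocsr(), directed=False)
    return A.tocsr()


class AdaptiveSpectralClustering(ClusterMixin, BaseEstimator):
    """Spectral clustering on the adaptive neighbourhood graph.

    Parameters
    ----------
    n_clusters : int, default 2
    n_components : int, optional
        Spectral embedding dimension; defaults to ``d*``.
    k_fixed : int, optional
        Force a constant neighbourhood size (the standard kNN spectral
        clustering baseline); requires ``n_components``.
    row_normalize : bool, default False
        Normalise embedding rows to unit length before K-means.
    n_init : int, default 10
        K-means restarts.
    random_state : int, default 0
    tau, alpha, k_min, k_max, init_k, tol, max_iter
        Forwarded to :class:`~adaptive_manifold.idestimate.ABIDE`.

    Attributes
    ----------
    labels_ : (n,) int array
    embedding_ : (n, n_components_) array
    inertia_ : float, K-means objective at the solution
    abide_ : fitted ABIDE instance (absent with ``k_fixed``)
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_components: int | None = None,
        k_fixed: int | None = None,
        row_normalize: bool = False,
        n_init: int = 10,
        random_state: int = 0,
        tau: float = 0.5,
        alpha: float = 0.01,
        k_min: int = 3,
        k_max: int = 100,
        init_k: int = 10,
        tol: float = 1e-3,
        max_iter: int = 50,
    ):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.k_fixed = k_fixed
        self.row_normalize = row_normalize
        self.n_init = n_init
        self.random_state = random_state
        self.tau = tau
        self.alpha = alpha
        self.k_min = k_min
        self.k_max = k_max
        self.init_k = init_k
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be at least 2")
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
            else max(self.abide_.d_star_, 1)
        )
        A = symmetrize(adaptive_adjacency(table, k_star), "union")
        if connected_components(A, directed=False)[0] > 1:
            A = repair_connectivity(A, X)
        self.affinity_ = A
        self.embedding_ = spectral_embed(
            A, self.n_components_, row_normalize=self.row_normalize
        )
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(self.embedding_)
        self.labels_ = km.labels_
        self.inertia_ = float(km.inertia_)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def sc_star(X, n_clusters: int, **params):
    """Functional wrapper returning (labels, embedding, fitted estimator)."""
    model = AdaptiveSpectralClustering(n_clusters=n_clusters, **params).fit(X)
    return model.labels_, model.embedding_, model
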