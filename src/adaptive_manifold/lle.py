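"""Locally adaptive LLE.

Classical LLE reconstructs every point as a convex-ish (sum-to-one)
combination of a *fixed* number of neighbours and finds low-dimensional
coordinates preserving those weights.  Here both free hyper-parameters are
supplied by the adaptive dimension estimator: each point uses its own
``k*_i`` neighbours and the target dimension defaults to ``d*``.

The embedding solves

    min_Y  sum_i || y_i - sum_j W_ij y_j ||^2
    s.t.   (1/n) Y'Y = I,   sum_i y_i = 0,

via the bottom eigenvectors of ``M = (I - W)'(I - W)``; the constant
eigenvector is discarded and the rest are scaled by ``sqrt(n)`` so the
unit-covariance constraint holds literally.

Out-of-sample points are projected with the same machinery: the point's
own ``k*`` is estimated from its distances to the training set at the
trained dimension, reconstruction weights are solved on those neighbours,
and the embedding is the weighted combination of their training
coordinates.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh, solve
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import ArpackError, eigsh
from scipy.stats import chi2
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import pairwise_distances
from sklearn.utils.validation import check_is_fitted

from .graphs import adaptive_adjacency
from .idestimate import ABIDE, AdaptiveNeighborhood
from .neighbors import _validate_matrix

__all__ = ["AdaptiveLLE", "local_weights", "assemble_weight_matrix", "lle_embed"]


def local_weights(
    X: np.ndarray, i: int, nbrs: np.ndarray, reg: float = 1e-3
) -> np.ndarray:
    """Sum-to-one least-squares reconstruction weights of point ``i``.

    Solves the local Gram system ``G w = 1`` and normalises, which is the
    closed form of the constrained problem.  When the neighbourhood is
    larger than the feature dimension (or the Gram matrix is otherwise
    singular) a ridge ``reg * trace(G) / k`` conditions the system.

    The scikit-learn LLE solver uses the same ridge without the ``1 / k``
    factor; passing ``reg = k * 1e-3`` therefore reproduces its weights
    exactly on a fixed-k graph.
    """
    nbrs = np.asarray(nbrs, dtype=np.int64)
    if nbrs.size == 0:
        raise ValueError("empty neighbourhood")
    Z = X[nbrs] - X[i]
    return _solve_weights(Z, reg)


def _solve_weights(Z: np.ndarray, reg: float) -> np.ndarray:
    k, D = Z.shape
    G = Z @ Z.T
    tr = np.trace(G)
    ridge = reg * tr / k if tr > 0 else reg
    needs_ridge = k > D or np.linalg.matrix_rank(G) < k
    if needs_ridge:
        G.flat[:: k + 1] += ridge
    ones = np.ones(k)
    try:
        w = solve(G, ones, assume_a="pos")
    except np.linalg.LinAlgError:
        G.flat[:: k + 1] += ridge
        w = solve(G, ones, assume_a="pos")
    return w / w.sum()


def assemble_weight_matrix(
    X: np.ndarray, A: sp.spmatrix, reg: float = 1e-3
) -> sp.csr_matrix:
    """Row-stochastic reconstruction-weight matrix on the adjacency support."""
    A = sp.csr_matrix(A)
    n = A.shape[0]
    X = np.asarray(X, dtype=float)
    data = np.empty_like(A.data, dtype=float)
    for i in range(n):
        sl = slice(A.indptr[i], A.indptr[i + 1])
        nbrs = A.indices[sl]
        if nbrs.size == 0:
            raise ValueError(f"point {i} has no neighbours in the adjacency")
        data[sl] = local_weights(X, i, nbrs, reg=reg)
    return sp.csr_matrix((data, A.indices.copy(), A.indptr.copy()), shape=(n, n))


def _bottom_eigvecs(M, n_keep: int, dense: bool):
    if dense:
        Md = M.toarray() if sp.issparse(M) else np.asarray(M)
        vals, vecs = eigh(Md, subset_by_index=(0, n_keep - 1))
    else:
        try:
            vals, vecs = eigsh(M, k=n_keep, sigma=0.0, which="LM")
        except (ArpackError, RuntimeError):
            Md = M.toarray()
            vals, vecs = eigh(Md, subset_by_index=(0, n_keep - 1))
    order = np.argsort(vals)
    return vals[order], vecs[:, order]


def lle_embed(
    W: sp.spmatrix, d_proj: int, dense_threshold: int = 500
) -> tuple[np.ndarray, float]:
    """Constrained eigen-embedding from a row-stochastic weight matrix.

    Returns ``(Y, cost)`` where ``Y`` is ``n x d_proj`` satisfying the
    centering and unit-covariance constraints, and ``cost`` is the attained
    reconstruction error ``sum_i ||y_i - sum_j W_ij y_j||^2`` (``n`` times
    the sum of the retained eigenvalues).

    If the weight graph is disconnected only the largest weakly connected
    component is embedded; remaining rows are NaN and a warning names the
    count.
    """
    W = sp.csr_matrix(W)
    n = W.shape[0]
    if d_proj > n - 2:
        raise ValueError("d_proj must be at most n - 2")
    n_comp, comp = connected_components(W, directed=True, connection="weak")
    if n_comp > 1:
        sizes = np.bincount(comp)
        keep = np.flatnonzero(comp == sizes.argmax())
        warnings.warn(
            f"weight graph has {n_comp} components; embedding the largest "
            f"({keep.size} points), {n - keep.size} left unembedded (NaN)"
        )
        Wk = W[keep][:, keep]
        # renormalise rows that lost mass to other components
        rs = np.asarray(Wk.sum(axis=1)).ravel()
        rs[rs == 0] = 1.0
        Wk = sp.diags(1.0 / rs) @ Wk
        Yk, cost = lle_embed(Wk, d_proj, dense_threshold)
        Y = np.full((n, d_proj), np.nan)
        Y[keep] = Yk
        return Y, cost
    I_W = sp.eye(n, format="csr") - W
    M = (I_W.T @ I_W).tocsc()
    try:
        vals, vecs = _bottom_eigvecs(M, d_proj + 1, dense=n < dense_threshold)
    except Exception as exc:  # pragma: no cover - solver failure path
        raise RuntimeError(
            "eigen-solver failed; consider densifying the neighbourhood graph"
        ) from exc
    # The constant vector spans the trivial null direction of (I - W).  With
    # near-degenerate bottom eigenvalues the solver may mix it into the other
    # eigenvectors, so instead of dropping column 0 blindly we project the
    # constant direction out of the whole bottom block and re-orthonormalise,
    # which enforces both printed constraints to machine precision.
    ones = np.full(n, 1.0 / np.sqrt(n))
    B = vecs - np.outer(ones, ones @ vecs)
    U, s, _ = np.linalg.svd(B, full_matrices=False)
    Y = U[:, :d_proj] * np.sqrt(n)
    cost = float(n * vals[1 : d_proj + 1].sum())
    return Y, cost


class AdaptiveLLE(TransformerMixin, BaseEstimator):
    """LLE with data-driven neighbourhood sizes and target dimension.

    Parameters
    ----------
    n_components : int, optional
        Embedding dimension; defaults to the rounded intrinsic-dimension
        estimate ``d*`` (set e.g. ``n_components=2`` for visualisation).
    reg : float, default 1e-3
        Ridge coefficient of the local Gram systems (times ``trace(G)``).
    k_fixed : int, optional
        Force a constant neighbourhood size instead of the adaptive scan —
        the classical-LLE degeneration used as a baseline.  Requires
        ``n_components`` when the dimension estimate is skipped.
    tau, alpha, k_min, k_max, init_k, tol, max_iter
        Forwarded to :class:`~adaptive_manifold.idestimate.ABIDE`.

    Attributes
    ----------
    embedding_ : (n, n_components_) array
    abide_ : fitted ABIDE instance (absent when ``k_fixed`` skips it)
    k_star_ : (n,) int array of neighbourhood sizes actually used
    weights_ : sparse row-stochastic reconstruction weights
    cost_ : float, attained reconstruction error
    """

    def __init__(
        self,
        n_components: int | None = None,
        reg: float = 1e-3,
        k_fixed: int | None = None,
        tau: float = 0.5,
        alpha: float = 0.01,
        k_min: int = 3,
        k_max: int = 100,
        init_k: int = 10,
        tol: float = 1e-3,
        max_iter: int = 50,
    ):
        self.n_components = n_components
        self.reg = reg
        self.k_fixed = k_fixed
        self.tau = tau
        self.alpha = alpha
        self.k_min = k_min
        self.k_max = k_max
        self.init_k = init_k
        self.tol = tol
        self.max_iter = max_iter

    def _abide(self) -> ABIDE:
        return ABIDE(
            tau=self.tau,
            alpha=self.alpha,
            k_min=self.k_min,
            k_max=self.k_max,
            init_k=self.init_k,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    def fit(self, X, y=None):
        X = _validate_matrix(X)
        self.X_train_ = X
        n = X.shape[0]
        if self.k_fixed is not None and self.n_components is not None:
            from .neighbors import build_neighbor_table

            self.neighbor_table_ = build_neighbor_table(
                X, max(self.k_fixed, min(self.k_max, n - 1))
            )
            self.k_star_ = np.full(n, self.k_fixed, dtype=np.int64)
            self.d_star_ = None
            self.d_hat_ = None
        else:
            est = self._abide().fit(X)
            self.abide_ = est
            self.neighbor_table_ = est.neighbor_table_
            self.d_star_ = est.d_star_
            self.d_hat_ = est.d_hat_
            self.k_star_ = (
                np.full(n, self.k_fixed, dtype=np.int64)
                if self.k_fixed is not None
                else est.k_star_
            )
        self.n_components_ = (
            self.n_components if self.n_components is not None else max(self.d_star_, 1)
        )
        A = adaptive_adjacency(self.neighbor_table_, self.k_star_)
        self.adjacency_ = A
        self.weights_ = assemble_weight_matrix(X, A, reg=self.reg)
        self.embedding_, self.cost_ = lle_embed(self.weights_, self.n_components_)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def _kstar_test(self, dists_sorted: np.ndarray, nbr_order: np.ndarray) -> int:
        """Adaptive neighbourhood size of one out-of-sample point.

        Runs the same likelihood-ratio first-crossing scan as training,
        at the trained dimension, using the test point's ordered distances
        and each ``(k+1)``-th neighbour's own k-th training radius.
        """
        d = self.d_hat_ if self.d_hat_ is not None else float(self.n_components_)
        k_cap = self.neighbor_table_.k_max
        d_thr = float(chi2.ppf(1.0 - self.alpha, df=1))
        ks = np.arange(self.k_min, k_cap)
        r_i = dists_sorted[ks - 1]
        r_j = self.neighbor_table_.distances[nbr_order[ks], ks - 1]
        lo = np.minimum(r_i, r_j)
        hi = np.maximum(r_i, r_j)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = (lo / hi) ** d
        D = 2.0 * ks * (2.0 * np.log1p(u) - np.log(4.0 * u))
        D[~np.isfinite(D)] = 0.0
        hit = np.flatnonzero(D >= d_thr)
        return int(ks[hit[0]]) if hit.size else int(k_cap)

    def transform(self, X) -> np.ndarray:
        """Project out-of-sample points into the trained embedding."""
        check_is_fitted(self, "embedding_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.X_train_.shape[1]:
            raise ValueError(
                f"feature mismatch: got {X.shape[1]}, trained on "
                f"{self.X_train_.shape[1]}"
            )
        dist = pairwise_distances(X, self.X_train_)
        Y_out = np.empty((X.shape[0], self.n_components_))
        for t in range(X.shape[0]):
            order = np.lexsort((np.arange(dist.shape[1]), dist[t]))
            d_sorted = dist[t, order]
            if self.k_fixed is not None:
                k_t = self.k_fixed
            else:
                k_t = self._kstar_test(d_sorted, order)
            nbrs = order[:k_t]
            Z = self.X_train_[nbrs] - X[t]
            w = _solve_weights(Z, self.reg)
            Y_out[t] = w @ self.embedding_[nbrs]
        return Y_out


def lle_star_fit(X, **params):
    """Functional wrapper returning (embedding, estimator)."""
    model = AdaptiveLLE(**params).fit(X)
    return model.embedding_, model
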