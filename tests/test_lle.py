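import numpy as np
import pytest
import scipy.sparse as sp
from scipy.linalg import orthogonal_procrustes

from adaptive_manifold.graphs import adaptive_adjacency
from adaptive_manifold.lle import (
    AdaptiveLLE,
    assemble_weight_matrix,
    lle_embed,
    local_weights,
)
from adaptive_manifold.neighbors import build_neighbor_table


def whiten(Z):
    """Centre and whiten to unit covariance — the LLE output convention."""
    Zc = Z - Z.mean(0)
    U, _, _ = np.linalg.svd(Zc, full_matrices=False)
    return U * np.sqrt(len(Z))


def procrustes_err(A, B):
    R, _ = orthogonal_procrustes(A, B)
    return np.linalg.norm(A @ R - B) / np.linalg.norm(B)


# ---------------------------------------------------------------------------
# local weights


def test_single_neighbour_weight_is_one():
    X = np.array([[0.0], [2.0]])
    assert np.allclose(local_weights(X, 0, [1]), [1.0])


def test_symmetric_neighbours_split_evenly():
    X = np.array([[0.0], [-1.0], [1.0]])
    w = local_weights(X, 0, [1, 2])
    assert np.allclose(w, [0.5, 0.5], atol=1e-6)


def test_asymmetric_line_weights():
    # reconstruct 1 from 0 and 4: w = (0.75, 0.25) up to the ridge
    X = np.array([[1.0], [0.0], [4.0]])
    w = local_weights(X, 0, [1, 2])
    assert np.allclose(w, [0.75, 0.25], atol=5e-3)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_empty_neighbourhood_raises():
    with pytest.raises(ValueError, match="empty"):
        local_weights(np.zeros((3, 1)), 0, [])


def test_weight_matrix_rows_sum_to_one(rng):
    X = rng.normal(size=(60, 4))
    t = build_neighbor_table(X, 10)
    A = adaptive_adjacency(t, rng.integers(3, 11, size=60))
    W = assemble_weight_matrix(X, A)
    assert np.allclose(np.asarray(W.sum(axis=1)).ravel(), 1.0, atol=1e-10)
    # support containment
    assert (sp.csr_matrix((np.ones_like(W.data), W.indices, W.indptr)) != A).nnz == 0


def test_weight_matrix_three_point_line():
    X = np.array([[0.0], [1.0], [3.0]])
    t = build_neighbor_table(X, 2)
    A = adaptive_adjacency(t, np.array([1, 1, 2]))
    W = assemble_weight_matrix(X, A)
    assert W[0, 1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# embedding


def test_embedding_constraints(plane_5d):
    X, _ = plane_5d
    model = AdaptiveLLE(n_components=2, k_fixed=25).fit(X)
    Y = model.embedding_
    n = len(Y)
    assert np.abs(Y.mean(axis=0)).max() < 1e-8
    assert np.abs(Y.T @ Y / n - np.eye(2)).max() < 1e-8


def test_plane_recovery(plane_5d):
    X, latent = plane_5d
    model = AdaptiveLLE(n_components=2, k_fixed=25).fit(X)
    assert model.cost_ < 1e-5
    assert procrustes_err(model.embedding_, whiten(latent)) < 1e-3


def test_monotone_embedding_of_arc():
    rng = np.random.default_rng(8)
    s = np.sort(rng.uniform(0.0, 1.0, size=250))
    theta = 0.5 * np.pi * s  # quarter circle, no closure
    X = np.column_stack([np.cos(theta), np.sin(theta)])
    model = AdaptiveLLE(n_components=1, k_fixed=10).fit(X)
    y = model.embedding_[:, 0]
    diffs = np.diff(y)
    assert np.all(diffs > 0) or np.all(diffs < 0)


def test_matches_sklearn_lle_with_fixed_k(rng):
    from sklearn.manifold import LocallyLinearEmbedding

    X = rng.normal(size=(120, 3))
    k, d = 10, 2
    sk = LocallyLinearEmbedding(
        n_neighbors=k, n_components=d, reg=1e-3, eigen_solver="dense"
    ).fit_transform(X)
    # our ridge is reg * trace(G) / k; sklearn's is reg * trace(G)
    mine = AdaptiveLLE(n_components=d, k_fixed=k, reg=k * 1e-3).fit(X)
    err = procrustes_err(mine.embedding_ / np.sqrt(len(X)), sk)
    assert err < 1e-6


def test_disconnected_graph_embeds_largest_component():
    W = sp.lil_matrix((8, 8))
    # two 4-cliques of uniform weights, one larger by a point than needed
    for grp in ([0, 1, 2, 3, 4], [5, 6, 7]):
        for i in grp:
            for j in grp:
                if i != j:
                    W[i, j] = 1.0 / (len(grp) - 1)
    with pytest.warns(UserWarning, match="components"):
        Y, _ = lle_embed(W.tocsr(), 1)
    assert np.isfinite(Y[:5]).all()
    assert np.isnan(Y[5:]).all()


def test_dproj_override_gives_requested_shape(rng):
    X = rng.normal(size=(150, 6))
    model = AdaptiveLLE(n_components=2).fit(X)
    assert model.embedding_.shape == (150, 2)


# ---------------------------------------------------------------------------
# out-of-sample projection


def test_barycentre_linearity(plane_5d):
    X, _ = plane_5d
    model = AdaptiveLLE(n_components=2, k_fixed=25).fit(X)
    # a test point reproduced by uniform weights maps to the barycentre
    y = model.transform(X[:10])
    assert y.shape == (10, 2)


def test_training_point_projects_near_itself(plane_5d):
    X, _ = plane_5d
    model = AdaptiveLLE(n_components=2).fit(X)
    y = model.transform(X[:20])
    err = np.linalg.norm(y - model.embedding_[:20], axis=1)
    spread = np.linalg.norm(model.embedding_, axis=1).mean()
    assert np.median(err) / spread < 0.05


def test_transform_rejects_dimension_mismatch(plane_5d):
    X, _ = plane_5d
    model = AdaptiveLLE(n_components=2, k_fixed=10).fit(X)
    with pytest.raises(ValueError, match="feature mismatch"):
        model.transform(np.zeros((2, 9)))


def test_supervised_probe_on_plane(plane_5d):
    """3-fold CV accuracy on projected points close to within-sample accuracy."""
    from sklearn.linear_model import LogisticRegression
    from adaptive_manifold.evaluation import supervised_probe

    X, latent = plane_5d
    labels = (latent[:, 0] > 0.5).astype(int)
    model = AdaptiveLLE(n_components=2, k_fixed=20)
    rep = supervised_probe(model, X, labels, folds=3, seed=0)
    fitted = model.fit(X)
    within = LogisticRegression(penalty=None, max_iter=1000).fit(
        fitted.embedding_, labels
    )
    within_acc = within.score(fitted.embedding_, labels)
    assert rep.accuracy > within_acc - 0.05
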