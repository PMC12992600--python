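"""Clustering and supervised evaluation harness.

Mirrors the benchmark protocol used throughout this package's
experiments: K-means (as many clusters as ground-truth labels, 10
restarts) on an embedding, scored by external agreement indices
(ARI, homogeneity, completeness, V-measure); grid-search baselines over
fixed neighbourhood sizes; and a 3-fold unpenalised logistic-regression
probe on out-of-sample projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _m
from sklearn.base import clone
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "MetricsReport",
    "clustering_metrics",
    "kmeans_evaluate",
    "grid_search_baseline",
    "supervised_probe",
    "probe_embedding",
]


@dataclass
class MetricsReport:
    ari: float | None = None
    homogeneity: float | None = None
    completeness: float | None = None
    v_measure: float | None = None
    accuracy: float | None = None
    f1: float | None = None
    config: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k != "config" and v is not None
        }
        out.update({f"config.{k}": v for k, v in self.config.items()})
        return out


def clustering_metrics(truth, pred, **config) -> MetricsReport:
    """External agreement between a predicted partition and ground truth.

    Standard contingency-table definitions; invariant to relabelling of
    the predicted cluster ids.  V-measure is the harmonic mean of
    homogeneity and completeness.
    """
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.shape != pred.shape:
        raise ValueError("label vectors must have equal length")
    if truth.size < 2:
        raise ValueError("need at least two points")
    h, c, v = _m.homogeneity_completeness_v_measure(truth, pred)
    return MetricsReport(
        ari=float(_m.adjusted_rand_score(truth, pred)),
        homogeneity=float(h),
        completeness=float(c),
        v_measure=float(v),
        config=config,
    )


def kmeans_evaluate(
    embedding: np.ndarray, truth, seed: int = 0, n_init: int = 10, **config
) -> MetricsReport:
    """K-means on an embedding with as many clusters as true labels, then score."""
    truth = np.asarray(truth).ravel()
    n_clusters = np.unique(truth).size
    emb = np.asarray(embedding, dtype=float)
    ok = np.all(np.isfinite(emb), axis=1)  # skip unembedded (NaN) rows
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(emb[ok])
    rep = clustering_metrics(
        truth[ok], labels, n_clusters=n_clusters, seed=seed, **config
    )
    return rep


def grid_search_baseline(
    X: np.ndarray,
    truth,
    method: str,
    k_grid,
    d_grid,
    seed: int = 0,
    comparator: tuple | None = None,
) -> list[MetricsReport]:
    """Fixed-k baselines of the adaptive embedders over a hyper-parameter grid.

    ``method`` is one of ``"lle"``, ``"spectral"``, ``"umap"``; every
    ``(k, d)`` cell runs the non-adaptive pipeline (constant neighbourhood
    size ``k``, target dimension ``d``) and is scored with
    :func:`kmeans_evaluate`.  Per-cell failures are recorded in the
    returned report's config and the sweep continues.  ``comparator``
    optionally marks the cell matching a summary statistic of the
    adaptive fit, e.g. ``(median k*, d*)``.
    """
    from .lle import AdaptiveLLE
    from .spectral import AdaptiveSpectralClustering
    from .umap_adaptive import AdaptiveUMAP

    truth = np.asarray(truth).ravel()
    n_clusters = np.unique(truth).size
    out: list[MetricsReport] = []
    for k in k_grid:
        for d in d_grid:
            cfg = {"method": method, "k": int(k), "d": int(d)}
            if comparator is not None and (int(k), int(d)) == tuple(map(int, comparator)):
                cfg["comparator"] = True
            try:
                if method == "lle":
                    emb = AdaptiveLLE(n_components=d, k_fixed=k).fit(X).embedding_
                    rep = kmeans_evaluate(emb, truth, seed=seed, **cfg)
                elif method == "spectral":
                    model = AdaptiveSpectralClustering(
                        n_clusters=n_clusters,
                        n_components=d,
                        k_fixed=k,
                        random_state=seed,
                    ).fit(X)
                    rep = clustering_metrics(truth, model.labels_, **cfg)
                elif method == "umap":
                    emb = (
                        AdaptiveUMAP(
                            n_components=d, k_fixed=k, random_state=seed
                        )
                        .fit(X)
                        .embedding_
                    )
                    rep = kmeans_evaluate(emb, truth, seed=seed, **cfg)
                else:
                    raise ValueError(f"unknown method {method!r}")
            except ValueError:
                raise
            except Exception as exc:  # record and continue
                rep = MetricsReport(config={**cfg, "error": repr(exc)})
            out.append(rep)
    return out


def probe_embedding(
    embedding: np.ndarray, labels, folds: int = 3, seed: int = 0
) -> MetricsReport:
    """Cross-validated unpenalised logistic regression on a fixed embedding."""
    labels = np.asarray(labels).ravel()
    if folds < 2:
        raise ValueError("folds must be at least 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, f1s = [], []
    for tr, te in skf.split(embedding, labels):
        clf = LogisticRegression(penalty=None, max_iter=1000)
        clf.fit(embedding[tr], labels[tr])
        pred = clf.predict(embedding[te])
        accs.append(_m.accuracy_score(labels[te], pred))
        f1s.append(_m.f1_score(labels[te], pred, average="macro"))
    return MetricsReport(
        accuracy=float(np.mean(accs)),
        f1=float(np.mean(f1s)),
        config={"folds": folds, "seed": seed},
    )


def supervised_probe(
    estimator, X: np.ndarray, labels, folds: int = 3, seed: int = 0
) -> MetricsReport:
    """The full supervised protocol on an adaptive embedder.

    Per fold: fit the embedder on the training split, project the held-out
    split out-of-sample, train an unpenalised multinomial logistic
    regression on the training embedding and score it on the projected
    test points.  Reports mean accuracy and macro F1 over stratified
    folds.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).ravel()
    if folds < 2:
        raise ValueError("folds must be at least 2")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, f1s = [], []
    for tr, te in skf.split(X, labels):
        model = clone(estimator).fit(X[tr])
        E_train = model.embedding_
        E_test = model.transform(X[te])
        clf = LogisticRegression(penalty=None, max_iter=1000)
        clf.fit(E_train, labels[tr])
        pred = clf.predict(E_test)
        accs.append(_m.accuracy_score(labels[te], pred))
        f1s.append(_m.f1_score(labels[te], pred, average="macro"))
    return MetricsReport(
        accuracy=float(np.mean(accs)),
        f1=float(np.mean(f1s)),
        config={"folds": folds, "seed": seed},
    )
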