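"""Exact nearest-neighbour tables.

Every likelihood and graph in this package is built from the sorted
Euclidean neighbour distances ``r[i, j]`` (distance from point ``i`` to its
``(j+1)``-th nearest neighbour, the point itself excluded).  The table is
computed exactly — the dimension estimator is a likelihood on the ordered
radii, so approximate neighbours would bias it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import pairwise_distances

__all__ = ["NeighborTable", "build_neighbor_table", "read_matrix"]


@dataclass(frozen=True)
class NeighborTable:
    """Sorted nearest-neighbour structure of a data matrix.

    Attributes
    ----------
    indices : (n, k_max) int array
        ``indices[i, j]`` is the index of the ``(j+1)``-th nearest
        neighbour of point ``i`` (self excluded).
    distances : (n, k_max) float array
        The matching Euclidean distances, non-decreasing along each row.
    """

    indices: np.ndarray
    distances: np.ndarray

    @property
    def n(self) -> int:
        return self.indices.shape[0]

    @property
    def k_max(self) -> int:
        return self.indices.shape[1]

    def __post_init__(self) -> None:
        if self.indices.shape != self.distances.shape:
            raise ValueError("indices and distances must have the same shape")


def _validate_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("expected a 2-D data matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least two observations")
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite entries")
    return X


def build_neighbor_table(X: np.ndarray, k_max: int) -> NeighborTable:
    """Compute the exact sorted ``k_max``-nearest-neighbour table.

    Ties in distance are broken by ascending point index so that every
    downstream structure (adjacency, weights, likelihood scans) is
    reproducible.  Coincident points are retained: a duplicate appears as a
    neighbour at distance zero.

    Parameters
    ----------
    X : (n, D) array
        Data matrix, rows are observations.
    k_max : int
        Number of neighbours to record, ``1 <= k_max <= n - 1``.
    """
    X = _validate_matrix(X)
    n = X.shape[0]
    if not 1 <= k_max <= n - 1:
        raise ValueError(
            f"insufficient points: k_max={k_max} requires n >= k_max + 1, got n={n}"
        )
    # Full pairwise matrix with a stable lexicographic sort on
    # (distance, index): exact and deterministic under ties.  Memory is
    # O(n^2) which is fine at the problem sizes this package targets.
    D = pairwise_distances(X, metric="euclidean")
    np.fill_diagonal(D, np.inf)  # never report self
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), D), axis=1)
    idx = order[:, :k_max]
    dist = np.take_along_axis(D, idx, axis=1)
    # pairwise_distances can return tiny negatives from cancellation; clamp
    dist = np.maximum(dist, 0.0)
    return NeighborTable(indices=idx.astype(np.int64), distances=dist)


def read_matrix(path: str | Path, *, delimiter: str | None = None) -> np.ndarray:
    """Read a numeric matrix from delimited text (comma or tab).

    A single header row of non-numeric tokens is tolerated and skipped.
    Rows are observations; the file must be strictly rectangular.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines):
        fields = [f.strip() for f in ln.split(delimiter)]
        try:
            rows.append([float(f) for f in fields])
        except ValueError:
            if lineno == 0:
                continue  # header row
            raise ValueError(f"{path}:{lineno + 1}: non-numeric field")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
    return np.asarray(rows, dtype=float)
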