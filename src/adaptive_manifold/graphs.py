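"""Adaptive neighbourhood graphs.

The binary adjacency puts an edge from each point to its ``k*_i`` nearest
neighbours — row ``i`` has exactly ``k*_i`` ones and an empty diagonal.
The same sparse support later carries barycentric reconstruction weights
(adaptive LLE) or fuzzy membership weights (adaptive UMAP).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .idestimate import AdaptiveNeighborhood
from .neighbors import NeighborTable

__all__ = ["adaptive_adjacency", "symmetrize", "write_edge_list", "read_edge_list"]


def adaptive_adjacency(
    table: NeighborTable, neighborhood: AdaptiveNeighborhood | np.ndarray
) -> sp.csr_matrix:
    """Directed binary adjacency: row ``i`` marks the ``k*_i`` nearest neighbours.

    ``neighborhood`` may be a fitted :class:`AdaptiveNeighborhood` or a raw
    integer vector (e.g. a constant ``k`` to recover the classical kNN
    graph).
    """
    k_star = (
        neighborhood.k_star
        if isinstance(neighborhood, AdaptiveNeighborhood)
        else np.asarray(neighborhood, dtype=np.int64)
    )
    n = table.n
    if k_star.shape != (n,):
        raise ValueError("k_star length must match the table")
    if k_star.min() < 1 or k_star.max() > table.k_max:
        raise ValueError("k_star outside [1, k_max]")
    indptr = np.concatenate([[0], np.cumsum(k_star)])
    indices = np.concatenate([table.indices[i, : k_star[i]] for i in range(n)])
    data = np.ones(indices.size)
    return sp.csr_matrix((data, indices, indptr), shape=(n, n))


def symmetrize(G: sp.spmatrix, policy: str = "union") -> sp.csr_matrix:
    """Symmetrize a directed weighted graph.

    Policies: ``union`` takes ``max(w_ij, w_ji)`` on the union support,
    ``intersection`` keeps mutual edges only, ``mean`` averages the two
    directions, and ``fuzzy_union`` applies the probabilistic t-conorm
    ``w_ij + w_ji - w_ij * w_ji`` used for fuzzy membership graphs.
    """
    G = sp.csr_matrix(G)
    Gt = G.T.tocsr()
    if policy == "union":
        S = G.maximum(Gt)
    elif policy == "intersection":
        mutual = (G > 0).multiply(Gt > 0)
        S = G.maximum(Gt).multiply(mutual)
    elif policy == "mean":
        S = (G + Gt) * 0.5
    elif policy == "fuzzy_union":
        if G.nnz and (G.data.min() < 0 or G.data.max() > 1):
            raise ValueError("fuzzy_union requires weights in [0, 1]")
        # computed as 1 - (1-a)(1-b) so that an input weight of exactly 1
        # yields exactly 1 (the t-conorm's absorbing element)
        union = sp.coo_matrix(G.maximum(Gt))
        a = np.asarray(G[union.row, union.col]).ravel()
        b = np.asarray(Gt[union.row, union.col]).ravel()
        data = 1.0 - (1.0 - a) * (1.0 - b)
        S = sp.csr_matrix((data, (union.row, union.col)), shape=G.shape)
    else:
        raise ValueError(f"unknown symmetrization policy {policy!r}")
    S = sp.csr_matrix(S)
    S.eliminate_zeros()
    return S


def write_edge_list(G: sp.spmatrix, path: str | Path) -> None:
    """Write a graph as 3-column delimited text ``i<TAB>j<TAB>w`` (0-based)."""
    coo = sp.coo_matrix(G)
    with open(path, "w") as fh:
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{float(w)!r}\n")


def read_edge_list(path: str | Path, n: int | None = None) -> sp.csr_matrix:
    """Read a 3-column edge list written by :func:`write_edge_list`."""
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for ln in fh:
            if not ln.strip():
                continue
            i, j, w = ln.split()
            rows.append(int(i))
            cols.append(int(j))
            vals.append(float(w))
    if n is None:
        n = max(max(rows, default=-1), max(cols, default=-1)) + 1
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
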