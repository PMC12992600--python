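"""Joint intrinsic-dimension and adaptive-neighbourhood estimation.

The model: around each observation ``x_i`` the data are treated as a
realisation of a spatial Poisson process that is locally homogeneous.  Two
ingredients follow from this assumption.

* **Binomial dimension estimate (BIDE).**  Given concentric balls of radii
  ``r_A = tau * r_B`` around every point, the inner counts are
  conditionally binomial, ``k_A | k_B ~ Binomial(k_B, tau**d)``, and the
  maximum-likelihood intrinsic dimension has the closed form
  ``d_hat = log(sum k_A / sum k_B) / log(tau)``.

* **Likelihood-ratio neighbourhood scan.**  Under local homogeneity the
  hyper-spherical shell volumes between consecutive neighbour radii are
  i.i.d. exponential.  For growing ``k`` a likelihood-ratio statistic
  ``D[i, k]`` compares the shell intensity at ``x_i`` with the intensity at
  its ``(k+1)``-th neighbour; the adaptive neighbourhood size ``k*_i`` is
  the first ``k`` at which homogeneity is rejected against the chi-square(1)
  quantile.

The adaptive estimator (ABIDE) alternates the two until the dimension
stabilises, returning both the real-valued estimate ``d_hat`` (with its
integer rounding ``d_star``) and the per-point neighbourhood sizes
``k*_{1:n}`` that every adaptive embedder in this package consumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .neighbors import NeighborTable, build_neighbor_table, _validate_matrix

__all__ = [
    "AdaptiveNeighborhood",
    "BinomialCounts",
    "IDEstimate",
    "ShellVolumes",
    "ABIDE",
    "abide_fit",
    "abide_std",
    "bide_estimate",
    "counts_from_kstar",
    "lrt_statistic",
    "lrt_scan",
    "select_kstar",
    "shell_volumes",
    "unit_ball_volume",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class AdaptiveNeighborhood:
    """Per-point neighbourhood sizes ``k*`` plus scan diagnostics."""

    k_star: np.ndarray  # (n,) int
    alpha: float
    d_thr: float  # chi2_1 quantile used as rejection threshold
    capped: np.ndarray  # (n,) bool, True where the scan hit k_max


@dataclass(frozen=True)
class BinomialCounts:
    """Inner/outer ball counts feeding the binomial dimension estimate."""

    k_a: np.ndarray  # (n,) int, points within tau * r_B (centre excluded)
    k_b: np.ndarray  # (n,) int, points within r_B
    tau: float
    valid: np.ndarray = field(default=None)  # False where r_B collapsed to 0

    def __post_init__(self):
        if self.valid is None:
            object.__setattr__(self, "valid", np.ones(len(self.k_a), dtype=bool))


@dataclass(frozen=True)
class ShellVolumes:
    """Shell volumes ``v[i, j]`` and their cumulative sums ``V[i, k]``."""

    v: np.ndarray
    V: np.ndarray
    d_used: float


@dataclass(frozen=True)
class IDEstimate:
    """Result of an (adaptive) intrinsic-dimension fit."""

    d_hat: float
    d_star: int
    std: float
    trace: tuple
    converged: bool
    tau: float
    alpha: float


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# geometric primitives


def unit_ball_volume(d: float) -> float:
    """Volume of the unit ball in ``d`` dimensions, ``pi**(d/2) / Gamma(d/2 + 1)``.

    ``d`` may be any positive real; the expression interpolates between
    integer dimensions through the Gamma function.
    """
    if d <= 0:
        raise ValueError(f"dimension must be positive, got {d}")
    return float(np.exp(0.5 * d * np.log(np.pi) - gammaln(0.5 * d + 1.0)))


def shell_volumes(table: NeighborTable, d: float) -> ShellVolumes:
    """Hyper-spherical shell volumes between consecutive neighbour radii.

    ``v[i, j] = Omega_d * (r[i, j]**d - r[i, j-1]**d)`` with ``r[i, -1] := 0``;
    coincident neighbours produce zero-volume shells.  ``V`` accumulates the
    shells, telescoping to ``Omega_d * r[i, k]**d``.
    """
    if d <= 0:
        raise ValueError(f"dimension must be positive, got {d}")
    omega = unit_ball_volume(d)
    r_pow = table.distances**d
    v = np.diff(r_pow, axis=1, prepend=0.0) * omega
    v = np.maximum(v, 0.0)  # guard cancellation on near-ties
    return ShellVolumes(v=v, V=np.cumsum(v, axis=1), d_used=float(d))


# ---------------------------------------------------------------------------
# likelihood-ratio scan


def lrt_statistic(V_i: float, V_j: float, k: int) -> float:
    """Likelihood-ratio statistic for equal shell intensity at two points.

    ``V_i`` is the cumulative volume of the first ``k`` shells of a point,
    ``V_j`` the analogous volume at its ``(k+1)``-th neighbour.  Profiling
    the exponential log-likelihood ``k log(rho) - rho V`` under the pooled
    and free models yields the closed form
    ``D = 2k * log((V_i + V_j)**2 / (4 V_i V_j))`` which is asymptotically
    chi-square(1) under homogeneity.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if V_i <= 0 or V_j <= 0:
        raise ValueError("degenerate shells: cumulative volumes must be positive")
    return 2.0 * k * math.log((V_i + V_j) ** 2 / (4.0 * V_i * V_j))


def lrt_scan(table: NeighborTable, d: float, k_min: int, k_max: int) -> np.ndarray:
    """Vectorised ``D[i, k]`` for ``k = k_min .. k_max - 1``.

    The cumulative shell volume telescopes to ``Omega_d * r[i, k]**d``, so
    the statistic depends only on the ratio of the two k-th neighbour radii:
    with ``u = (min(r_i, r_j) / max(r_i, r_j))**d``,
    ``D = 2k * (2 log(1 + u) - log(4 u))``.  Rows where either radius is
    zero (coincident points) are reported as ``D = 0`` — zero-volume shells
    carry no likelihood information, which effectively merges duplicates
    forward until a positive shell appears.

    Returns an array of shape ``(n, k_max - k_min)``; column ``c``
    corresponds to ``k = k_min + c``.  The scan stops at ``k_max - 1``
    because the statistic at ``k`` needs the ``(k+1)``-th neighbour.
    """
    if d <= 0:
        raise ValueError("dimension must be positive")
    n, km = table.n, table.k_max
    if not 1 <= k_min < k_max <= km:
        raise ValueError("invalid k range")
    ks = np.arange(k_min, k_max)  # statistic computed for these k
    r_i = table.distances[:, ks - 1]  # k-th NN radius of i
    nbr = table.indices[:, ks]  # the (k+1)-th NN of i
    r_j = table.distances[nbr, ks - 1]  # its own k-th NN radius
    lo = np.minimum(r_i, r_j)
    hi = np.maximum(r_i, r_j)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (lo / hi) ** d
    D = 2.0 * ks * (2.0 * np.log1p(u) - np.log(4.0 * u))
    D[~np.isfinite(D)] = 0.0  # zero radii: no evidence either way
    return D


def select_kstar(
    table: NeighborTable,
    d: float,
    alpha: float = 0.01,
    k_min: int = 3,
    k_max: int | None = None,
) -> AdaptiveNeighborhood:
    """First-crossing neighbourhood selection.

    ``k*_i = min{k : D[i, k] >= q}`` with ``q`` the ``(1 - alpha)``-quantile
    of chi-square with one degree of freedom, scanning ``k_min .. k_max - 1``.
    Points where no ``k`` triggers keep ``k* = k_max`` and are flagged
    ``capped``.  Smaller ``alpha`` raises the threshold and therefore yields
    larger neighbourhoods.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if k_max is None:
        k_max = table.k_max
    d_thr = float(chi2.ppf(1.0 - alpha, df=1))
    D = lrt_scan(table, d, k_min, k_max)
    hit = D >= d_thr
    first = np.argmax(hit, axis=1)
    any_hit = hit.any(axis=1)
    k_star = np.where(any_hit, k_min + first, k_max).astype(np.int64)
    return AdaptiveNeighborhood(
        k_star=k_star, alpha=float(alpha), d_thr=d_thr, capped=~any_hit
    )


# ---------------------------------------------------------------------------
# binomial estimate


def counts_from_kstar(
    table: NeighborTable, neighborhood: AdaptiveNeighborhood, tau: float
) -> BinomialCounts:
    """Concentric-ball counts induced by the adaptive neighbourhoods.

    For each point the outer radius is its ``k*``-th neighbour distance,
    the inner radius ``tau`` times that, and the counts are taken with a
    closed boundary (``<=``).  Points whose outer radius is zero (all
    neighbours coincident) are excluded from the totals with a warning.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    k_star = neighborhood.k_star
    n = table.n
    rows = np.arange(n)
    r_b = table.distances[rows, k_star - 1]
    valid = r_b > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} point(s) with fully coincident "
            "neighbourhoods excluded from the binomial counts"
        )
    r_a = tau * r_b
    within = table.distances <= r_a[:, None]
    # only the first k*_i neighbours belong to the outer ball
    in_scope = np.arange(table.k_max)[None, :] < k_star[:, None]
    k_a = (within & in_scope).sum(axis=1)
    return BinomialCounts(
        k_a=k_a.astype(np.int64), k_b=k_star.copy(), tau=float(tau), valid=valid
    )


def bide_estimate(counts: BinomialCounts) -> float:
    """Closed-form binomial MLE of the intrinsic dimension.

    Maximises ``prod_i C(k_B_i, k_A_i) p**k_A_i (1-p)**(k_B_i - k_A_i)``
    with ``p = tau**d``, giving
    ``d_hat = log(sum k_A / sum k_B) / log(tau)``.
    """
    v = counts.valid
    s_a = int(counts.k_a[v].sum())
    s_b = int(counts.k_b[v].sum())
    if s_b <= 0:
        raise ValueError("no neighbours counted")
    if s_a == 0:
        raise ValueError("empty inner balls: increase tau or the neighbourhood size")
    if s_a > s_b:
        raise ValueError("inner count exceeds outer count")
    return math.log(s_a / s_b) / math.log(counts.tau)


def abide_std(counts: BinomialCounts, d_hat: float) -> float:
    """Delta-method standard deviation of the dimension estimate.

    Treats the pooled inner count as binomial with success probability
    ``p = tau**d_hat``; the resulting approximation
    ``sqrt((1 - p) / (p * sum(k_B) * log(tau)**2))`` ignores inter-point
    dependence and is reported as indicative only.
    """
    if d_hat <= 0:
        raise ValueError("d_hat must be positive")
    p = counts.tau**d_hat
    if not 0.0 < p < 1.0:
        raise ValueError("success probability degenerate (p is 0 or 1 numerically)")
    s_b = int(counts.k_b[counts.valid].sum())
    return math.sqrt((1.0 - p) / (p * s_b * math.log(counts.tau) ** 2))


# ---------------------------------------------------------------------------
# the estimator


class ABIDE(BaseEstimator):
    """Adaptive binomial intrinsic-dimension estimator.

    Alternates (a) the likelihood-ratio neighbourhood scan at the current
    dimension and (b) the closed-form binomial dimension estimate on the
    counts induced by the selected neighbourhoods, until the dimension
    changes by less than ``tol``.

    Parameters
    ----------
    tau : float, default 0.5
        Ratio of inner to outer ball radius.
    alpha : float, default 0.01
        Significance level of the homogeneity test; smaller values produce
        larger neighbourhoods.
    k_min : int, default 3
        Smallest neighbourhood size scanned (the statistic is too noisy
        below this).
    k_max : int, default 100
        Largest neighbourhood size; capped at ``n - 1``.
    init_k : int, default 10
        Fixed neighbourhood size used to seed the iteration with a
        one-shot binomial estimate when ``d_init`` is not given.
    d_init : float, optional
        Explicit starting dimension.
    tol : float, default 1e-3
        Convergence tolerance on successive dimension estimates.
    max_iter : int, default 50
        Iteration cap; on an oscillating scan the average of the last two
        iterates is returned with ``converged_ = False``.

    Attributes
    ----------
    d_hat_ : float
        Real-valued dimension estimate.
    d_star_ : int
        ``d_hat_`` rounded to the nearest integer (half away from zero).
    std_ : float
        Delta-method standard deviation.
    k_star_ : (n,) int array
        Adaptive neighbourhood sizes at convergence.
    capped_ : (n,) bool array
        Points whose scan never rejected homogeneity.
    trace_ : tuple of float
        Dimension iterates, starting from the initial value.
    converged_ : bool
    neighbor_table_ : NeighborTable
        The exact NN structure, reusable by downstream embedders.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = rng.uniform(size=(2000, 3)) @ np.eye(3, 10)
    >>> est = ABIDE().fit(X)
    >>> est.d_star_
    3
    """

    def __init__(
        self,
        tau: float = 0.5,
        alpha: float = 0.01,
        k_min: int = 3,
        k_max: int = 100,
        init_k: int = 10,
        d_init: float | None = None,
        tol: float = 1e-3,
        max_iter: int = 50,
    ):
        self.tau = tau
        self.alpha = alpha
        self.k_min = k_min
        self.k_max = k_max
        self.init_k = init_k
        self.d_init = d_init
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = _validate_matrix(X)
        n = X.shape[0]
        k_cap = min(self.k_max, n - 1)
        if self.k_min >= k_cap:
            raise ValueError("k_min must be smaller than the effective k_max")
        table = build_neighbor_table(X, k_cap)
        self.neighbor_table_ = table

        if self.d_init is not None:
            d = float(self.d_init)
        else:
            k0 = min(self.init_k, k_cap)
            fixed = AdaptiveNeighborhood(
                k_star=np.full(n, k0, dtype=np.int64),
                alpha=self.alpha,
                d_thr=np.nan,
                capped=np.zeros(n, dtype=bool),
            )
            d = bide_estimate(counts_from_kstar(table, fixed, self.tau))

        trace = [d]
        converged = False
        neighborhood = None
        counts = None
        for _ in range(self.max_iter):
            neighborhood = select_kstar(table, d, self.alpha, self.k_min, k_cap)
            counts = counts_from_kstar(table, neighborhood, self.tau)
            d_new = bide_estimate(counts)
            trace.append(d_new)
            if abs(d_new - d) <= self.tol:
                converged = True
                d = d_new
                break
            d = d_new
        if not converged:
            warnings.warn(
                "ABIDE did not converge; returning the average of the last "
                "two iterates"
            )
            d = 0.5 * (trace[-1] + trace[-2])

        self.d_hat_ = float(d)
        self.d_star_ = _round_half_away(self.d_hat_)
        self.std_ = abide_std(counts, self.d_hat_)
        self.k_star_ = neighborhood.k_star
        self.capped_ = neighborhood.capped
        self.neighborhood_ = neighborhood
        self.counts_ = counts
        self.trace_ = tuple(trace)
        self.converged_ = converged
        self.n_iter_ = len(trace) - 1
        return self

    def estimate_(self) -> IDEstimate:
        """The fitted result as an immutable record."""
        check_is_fitted(self, "d_hat_")
        return IDEstimate(
            d_hat=self.d_hat_,
            d_star=self.d_star_,
            std=self.std_,
            trace=self.trace_,
            converged=self.converged_,
            tau=self.tau,
            alpha=self.alpha,
        )


def abide_fit(X, **params) -> tuple[IDEstimate, AdaptiveNeighborhood]:
    """Functional wrapper: fit :class:`ABIDE` and return (estimate, neighbourhoods)."""
    est = ABIDE(**params).fit(X)
    return est.estimate_(), est.neighborhood_
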