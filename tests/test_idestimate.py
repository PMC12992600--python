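import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import gamma

from adaptive_manifold.idestimate import (
    ABIDE,
    AdaptiveNeighborhood,
    BinomialCounts,
    abide_std,
    bide_estimate,
    counts_from_kstar,
    lrt_statistic,
    select_kstar,
    shell_volumes,
    unit_ball_volume,
)
from adaptive_manifold.neighbors import NeighborTable, build_neighbor_table
from adaptive_manifold.synth import sample_hypercube


# ---------------------------------------------------------------------------
# geometric primitives


@pytest.mark.parametrize(
    "d, expected",
    [
        (1.0, 2.0),  # length of [-1, 1]
        (2.0, math.pi),  # unit disc
        (3.0, 4.0 * math.pi / 3.0),
        (2.5, math.pi**1.25 / gamma(2.25)),  # real-valued d via Gamma oracle
    ],
)
def test_unit_ball_volume(d, expected):
    assert unit_ball_volume(d) == pytest.approx(expected, rel=1e-12)


def test_unit_ball_volume_rejects_nonpositive():
    with pytest.raises(ValueError):
        unit_ball_volume(0.0)


def test_shell_volumes_disc_areas():
    t = NeighborTable(
        indices=np.array([[1, 2]]), distances=np.array([[1.0, 2.0]])
    )
    sv = shell_volumes(t, 2.0)
    assert np.allclose(sv.v[0], [math.pi, 3 * math.pi])
    assert np.allclose(sv.V[0], [math.pi, 4 * math.pi])


def test_shell_volumes_duplicate_radius_gives_zero_shell():
    t = NeighborTable(
        indices=np.array([[1, 2, 3]]), distances=np.array([[0.5, 0.5, 1.0]])
    )
    sv = shell_volumes(t, 3.0)
    assert sv.v[0, 1] == 0.0


def test_shell_volumes_telescoping(rng):
    radii = np.sort(rng.uniform(0.1, 2.0, size=(5, 8)), axis=1)
    t = NeighborTable(indices=np.zeros((5, 8), dtype=int), distances=radii)
    sv = shell_volumes(t, 3.0)
    omega3 = unit_ball_volume(3.0)
    assert np.allclose(sv.V, omega3 * radii**3, rtol=1e-10)


# ---------------------------------------------------------------------------
# likelihood-ratio statistic


def lrt_numerical(V_i, V_j, k):
    """Two-parameter vs pooled profile likelihood, maximised numerically."""

    def nll_free(rho):
        return -(k * math.log(rho) - rho * V_i)

    def nll_free2(rho):
        return -(k * math.log(rho) - rho * V_j)

    def nll_pooled(rho):
        return -(2 * k * math.log(rho) - rho * (V_i + V_j))

    opts = dict(method="bounded", options={"xatol": 1e-13})
    hi = 10 * k / min(V_i, V_j)
    m1 = minimize_scalar(nll_free, bounds=(1e-12, hi), **opts)
    m2 = minimize_scalar(nll_free2, bounds=(1e-12, hi), **opts)
    m0 = minimize_scalar(nll_pooled, bounds=(1e-12, hi), **opts)
    return -2.0 * (-m0.fun - (-m1.fun - m2.fun))


@pytest.mark.parametrize(
    "V_i, V_j, k, expected",
    [
        (2.0, 2.0, 7, 0.0),  # identical intensities
        (1.0, 3.0, 5, 10 * math.log(4.0 / 3.0)),
        (1.0, 10.0, 1, 2 * math.log(121.0 / 40.0)),
    ],
)
def test_lrt_closed_form_values(V_i, V_j, k, expected):
    assert lrt_statistic(V_i, V_j, k) == pytest.approx(expected, abs=1e-12)


def test_lrt_agrees_with_numerical_maximisation():
    rng = np.random.default_rng(7)
    for _ in range(100):
        V_i = rng.uniform(0.1, 5.0)
        V_j = rng.uniform(0.1, 5.0)
        k = int(rng.integers(1, 30))
        closed = lrt_statistic(V_i, V_j, k)
        assert closed >= 0.0
        assert closed == pytest.approx(lrt_numerical(V_i, V_j, k), abs=1e-8)


def test_lrt_zero_iff_equal_volumes(rng):
    V = rng.uniform(0.5, 2.0)
    assert lrt_statistic(V, V, 10) == 0.0
    assert lrt_statistic(V, V * 1.01, 10) > 0.0


def test_lrt_rejects_degenerate_volumes():
    with pytest.raises(ValueError, match="degenerate"):
        lrt_statistic(0.0, 1.0, 3)


# ---------------------------------------------------------------------------
# k* selection


def test_first_crossing_rule(monkeypatch):
    # a point whose D-sequence is (0.1, 0.5, 4.2, 9.0) for k = 1..4 must
    # select k* = 3 at alpha = 0.05 (chi2_1 0.95-quantile ~ 3.8415)
    from adaptive_manifold import idestimate

    D = np.array([[0.1, 0.5, 4.2, 9.0], [0.1, 0.2, 0.3, 0.4]])
    monkeypatch.setattr(idestimate, "lrt_scan", lambda *a, **k: D)
    t = NeighborTable(indices=np.zeros((2, 5), dtype=int), distances=np.ones((2, 5)))
    sel = select_kstar(t, d=2.0, alpha=0.05, k_min=1, k_max=5)
    assert sel.k_star[0] == 3
    assert not sel.capped[0]
    # no crossing: fall back to k_max, flagged
    assert sel.k_star[1] == 5
    assert sel.capped[1]
    assert sel.d_thr == pytest.approx(3.841458, abs=1e-5)


def test_smaller_alpha_gives_larger_neighbourhoods(rng):
    X = rng.normal(size=(300, 3))
    t = build_neighbor_table(X, 60)
    loose = select_kstar(t, d=3.0, alpha=0.2)
    strict = select_kstar(t, d=3.0, alpha=0.01)
    assert np.all(strict.k_star >= loose.k_star)


def test_select_kstar_validates_alpha(gaussian_cloud):
    t = build_neighbor_table(gaussian_cloud, 10)
    with pytest.raises(ValueError, match="alpha"):
        select_kstar(t, d=2.0, alpha=1.5)


# ---------------------------------------------------------------------------
# binomial estimate


def counts(k_a, k_b, tau):
    return BinomialCounts(
        k_a=np.asarray(k_a, dtype=np.int64),
        k_b=np.asarray(k_b, dtype=np.int64),
        tau=tau,
    )


def test_bide_closed_form_examples():
    assert bide_estimate(counts([10, 15], [10, 15], 0.5)) == 0.0
    assert bide_estimate(counts([25], [100], 0.5)) == pytest.approx(2.0, abs=1e-14)


def test_bide_equals_numerical_argmax():
    # golden-section argmax of the printed binomial likelihood in d
    from scipy.optimize import minimize_scalar

    rng = np.random.default_rng(11)
    for _ in range(20):
        tau = rng.uniform(0.2, 0.8)
        k_b = rng.integers(5, 50, size=12)
        d_true = rng.uniform(0.5, 6.0)
        k_a = rng.binomial(k_b, tau**d_true)
        if k_a.sum() == 0:
            continue
        c = counts(k_a, k_b, tau)

        def nll(d):
            p = tau**d
            return -(k_a.sum() * np.log(p) + (k_b.sum() - k_a.sum()) * np.log1p(-p))

        m = minimize_scalar(nll, bounds=(1e-9, 50.0), method="bounded",
                            options={"xatol": 1e-10})
        assert bide_estimate(c) == pytest.approx(m.x, abs=1e-6)


def test_bide_monte_carlo_consistency():
    rng = np.random.default_rng(2)
    k_b = np.full(5000, 40)
    k_a = rng.binomial(k_b, 0.5**3)
    d = bide_estimate(counts(k_a, k_b, 0.5))
    assert d == pytest.approx(3.0, abs=0.05)


def test_bide_errors():
    with pytest.raises(ValueError, match="empty inner balls"):
        bide_estimate(counts([0, 0], [5, 5], 0.5))


# ---------------------------------------------------------------------------
# counts from adaptive neighbourhoods


def neighborhood(k_star):
    k_star = np.asarray(k_star, dtype=np.int64)
    return AdaptiveNeighborhood(
        k_star=k_star, alpha=0.01, d_thr=6.63, capped=np.zeros(len(k_star), bool)
    )


def test_counts_direct_example():
    t = NeighborTable(
        indices=np.array([[1, 2, 3, 4]]),
        distances=np.array([[1.0, 2.0, 3.0, 4.0]]),
    )
    c = counts_from_kstar(t, neighborhood([4]), tau=0.5)
    assert c.k_b[0] == 4
    assert c.k_a[0] == 2  # r_A = 2, boundary counted by <=


def test_counts_closed_boundary():
    # tau * r_B = 3 exactly: the neighbour sitting on the inner-ball
    # boundary is counted (closed boundary), so kA -> kB as tau -> 1
    t = NeighborTable(
        indices=np.array([[1, 2, 3, 4]]),
        distances=np.array([[1.0, 2.0, 3.0, 4.0]]),
    )
    c = counts_from_kstar(t, neighborhood([4]), tau=0.75)
    assert c.k_a[0] == 3


def test_counts_match_brute_force_radius_count(rng):
    X = rng.normal(size=(100, 3))
    t = build_neighbor_table(X, 30)
    k_star = rng.integers(5, 31, size=100)
    c = counts_from_kstar(t, neighborhood(k_star), tau=0.6)
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    np.fill_diagonal(D, np.inf)
    for i in range(100):
        r_b = np.sort(D[i])[k_star[i] - 1]
        assert c.k_a[i] == np.sum(D[i] <= 0.6 * r_b)


def test_counts_exclude_fully_coincident_points():
    X = np.array([[0.0], [0.0], [0.0], [5.0], [6.0], [7.0]])
    t = build_neighbor_table(X, 2)
    with pytest.warns(UserWarning, match="coincident"):
        c = counts_from_kstar(t, neighborhood([2] * 6), tau=0.5)
    assert not c.valid[:3].any()
    assert c.valid[3:].all()


# ---------------------------------------------------------------------------
# standard deviation


def test_std_arithmetic_and_bootstrap():
    c = counts([2500], [10000], 0.5)
    val = abide_std(c, 2.0)
    assert val == pytest.approx(
        math.sqrt(0.75 / (0.25 * 10000 * math.log(0.5) ** 2)), rel=1e-12
    )
    assert val == pytest.approx(0.0250, abs=5e-4)
    # parametric bootstrap under the binomial model
    rng = np.random.default_rng(5)
    sims = rng.binomial(10000, 0.25, size=4000)
    d_hats = np.log(sims / 10000) / math.log(0.5)
    assert val == pytest.approx(d_hats.std(), rel=0.1)


def test_std_scaling_law():
    base = abide_std(counts([250], [1000], 0.5), 2.0)
    doubled = abide_std(counts([500], [2000], 0.5), 2.0)
    assert doubled == pytest.approx(base / math.sqrt(2), rel=1e-12)


# ---------------------------------------------------------------------------
# the full estimator


def test_abide_recovers_hypercube_dimension():
    rng = np.random.default_rng(0)
    X = sample_hypercube(2000, 3, 10, rng)
    est = ABIDE().fit(X)
    assert est.d_star_ == 3
    assert est.converged_


def test_abide_invariant_to_permutation_and_rotation():
    rng = np.random.default_rng(1)
    X = sample_hypercube(500, 2, 6, rng)
    ref = ABIDE().fit(X)
    perm = rng.permutation(500)
    est_p = ABIDE().fit(X[perm])
    assert est_p.d_hat_ == pytest.approx(ref.d_hat_, abs=1e-12)
    assert np.array_equal(est_p.k_star_, ref.k_star_[perm])
    Q = np.linalg.qr(rng.normal(size=(6, 6)))[0]
    est_r = ABIDE().fit(X @ Q)
    assert est_r.d_hat_ == pytest.approx(ref.d_hat_, abs=1e-6)


def test_abide_metadata_and_trace():
    rng = np.random.default_rng(4)
    X = sample_hypercube(400, 2, 5, rng)
    est = ABIDE(tau=0.4, alpha=0.05).fit(X)
    rec = est.estimate_()
    assert rec.tau == 0.4 and rec.alpha == 0.05
    assert len(rec.trace) == est.n_iter_ + 1
    assert rec.d_star == round(rec.d_hat)
    assert abs(rec.trace[-1] - rec.trace[-2]) <= est.tol
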