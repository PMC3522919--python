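"""Linguistic contexts and context-based fuzzy c-means."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsklm.granulation import (
    ContextSet,
    LinguisticContext,
    cfcm_cluster,
    context_membership,
    make_flexible_contexts,
    make_uniform_contexts,
)


# ---------------------------------------------------------------------------
# independent oracle: plain-loop CFCM (standard FCM when w == 1)
# ---------------------------------------------------------------------------

def cfcm_oracle(X, w, c, m, init, n_iter):
    """Brute-force alternation of the membership and center updates."""
    X = np.asarray(X, float)
    N, d = X.shape
    U = np.array(init, float)
    U = U * (np.asarray(w, float) / U.sum(axis=0))
    V = np.zeros((c, d))
    for _ in range(n_iter):
        for i in range(c):
            num = sum(U[i, k] ** m * X[k] for k in range(N))
            den = sum(U[i, k] ** m for k in range(N))
            V[i] = num / den
        for k in range(N):
            dist = [np.sqrt(((X[k] - V[j]) ** 2).sum()) for j in range(c)]
            for i in range(c):
                s = sum((dist[i] / dist[j]) ** (2.0 / (m - 1.0)) for j in range(c))
                U[i, k] = w[k] / s
    return U, V


# ---------------------------------------------------------------------------
# contexts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "y,expected",
    [(0.5, 1.0), (0.25, 0.5), (1.2, 0.0), (-0.1, 0.0), (0.75, 0.5)],
)
def test_triangular_membership(y, expected):
    ctx = LinguisticContext(0.0, 0.5, 1.0)
    assert context_membership(ctx, y) == pytest.approx(expected, abs=1e-15)


def test_membership_is_vectorised():
    ctx = LinguisticContext(0.0, 0.5, 1.0)
    got = ctx.membership(np.array([0.25, 0.5, 1.2]))
    assert np.allclose(got, [0.5, 1.0, 0.0])


def test_shouldered_boundary_contexts():
    ctxs = make_uniform_contexts(np.array([0.0, 1.0]), 3).contexts
    assert ctxs[0].membership(-0.5) == 1.0  # open left shoulder
    assert ctxs[2].membership(1.5) == 1.0   # open right shoulder
    assert ctxs[1].membership(1.5) == 0.0


def test_uniform_apexes_equally_spaced():
    cs = make_uniform_contexts(np.array([0.0, 0.3, 1.0]), 3)
    assert np.allclose(cs.modes(), [0.0, 0.5, 1.0])
    mid = cs.contexts[1]
    assert (mid.r_minus, mid.r_mode, mid.r_plus) == (0.0, 0.5, 1.0)


def test_two_context_memberships_interpolate():
    cs = make_uniform_contexts(np.array([0.0, 1.0]), 2)
    assert np.allclose(cs.memberships(0.25), [0.75, 0.25])


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError, match="degenerate output range"):
        make_uniform_contexts(np.full(10, 3.3), 3)
    with pytest.raises(ValueError, match="p = 2"):
        make_uniform_contexts(np.array([0.0, 1.0]), 1)
    with pytest.raises(ValueError, match="insufficient output spread"):
        # 90% of the mass at one value collapses interior quantile apexes
        make_flexible_contexts(np.r_[np.full(90, 0.1), np.full(10, 0.9)], 4)
    with pytest.raises(ValueError):
        LinguisticContext(1.0, 0.5, 0.0)


def test_flexible_apexes_track_quantiles(rng):
    y = rng.uniform(size=20_000)
    cs = make_flexible_contexts(y, 3)
    assert np.allclose(cs.modes(), [0.0, 0.5, 1.0], atol=0.02)

    y2 = np.r_[np.full(90, 0.1), np.full(10, 0.9)]
    cs2 = make_flexible_contexts(y2, 2)
    assert cs2.modes()[0] == pytest.approx(0.1)
    assert cs2.modes()[1] == pytest.approx(0.9)


def test_flexible_contexts_widen_in_sparse_tail(rng):
    """On right-skewed output the top flexible context spans more of the range
    than the top uniform context, relieving data scarcity in the tail."""
    y = rng.exponential(size=5_000)
    p = 4
    uni = make_uniform_contexts(y, p).modes()
    flex = make_flexible_contexts(y, p).modes()
    assert (flex[-1] - flex[-2]) > (flex[1] - flex[0])  # wider in the tail
    # flexible packs the dense low region tighter than equal spacing
    assert (flex[1] - flex[0]) < (uni[1] - uni[0])


@pytest.mark.parametrize("scheme", ["uniform", "flexible"])
@pytest.mark.parametrize("p", [2, 3, 4, 5, 6])
def test_partition_of_unity(scheme, p, rng):
    maker = make_uniform_contexts if scheme == "uniform" else make_flexible_contexts
    y = rng.normal(5.0, 2.0, size=500)
    cs = maker(y, p)
    q = rng.uniform(y.min(), y.max(), size=1000)
    total = cs.memberships(q).sum(axis=0)
    assert np.abs(total - 1.0).max() < 1e-12
    assert np.all(np.diff(cs.modes()) > 0)


def test_context_set_dict_round_trip(rng):
    cs = make_flexible_contexts(rng.normal(size=200), 4)
    back = ContextSet.from_dict(cs.to_dict())
    q = rng.uniform(*cs.output_range, size=50)
    assert np.array_equal(back.memberships(q), cs.memberships(q))
    assert back.contexts[0].left_shoulder and back.contexts[-1].right_shoulder


# ---------------------------------------------------------------------------
# CFCM clustering
# ---------------------------------------------------------------------------

def test_single_cluster_closed_form(rng):
    X = rng.normal(size=(12, 2))
    w = rng.uniform(0.1, 1.0, size=12)
    res = cfcm_cluster(X, w, c=1, m=2.0, seed=0)
    assert np.allclose(res.memberships[0], w)
    expected = (w**2 @ X) / (w**2).sum()
    assert np.allclose(res.centers[0], expected)


def test_equidistant_point_splits_its_weight():
    # symmetric 1-D instance: the middle point (w = 0.8) sits exactly halfway
    # between the two centers that the symmetric init produces
    X = np.array([[-1.0], [1.0], [0.0]])
    w = np.array([1.0, 1.0, 0.8])
    init = np.array([[1.0, 0.0, 0.4], [0.0, 1.0, 0.4]])
    res = cfcm_cluster(X, w, c=2, m=2.0, init=init, max_iter=1)
    assert np.allclose(res.memberships[:, 2], [0.4, 0.4])


def test_matches_brute_force_oracle(rng):
    """Vectorised CFCM equals a plain-loop re-implementation run from the
    same initial memberships (10 fixed 2-D points, context weights)."""
    X = rng.normal(size=(10, 2))
    w = LinguisticContext(0.0, 0.5, 1.0).membership(rng.uniform(size=10))
    w = np.clip(w, 0.05, 1.0)  # keep every point in the context's support
    init = rng.uniform(size=(2, 10))
    res = cfcm_cluster(X, w, c=2, m=2.0, tol=1e-12, max_iter=300, init=init.copy())
    _, V = cfcm_oracle(X, w, c=2, m=2.0, init=init, n_iter=res.iterations)
    assert np.abs(res.centers - V).max() < 1e-8


def test_reduces_to_standard_fcm_when_unweighted(rng):
    X = rng.normal(size=(10, 2))
    w = np.ones(10)
    init = rng.uniform(size=(3, 10))
    res = cfcm_cluster(X, w, c=3, m=2.0, tol=1e-12, max_iter=300, init=init.copy())
    U, V = cfcm_oracle(X, w, c=3, m=2.0, init=init, n_iter=res.iterations)
    assert np.abs(res.centers - V).max() < 1e-8
    assert np.abs(res.memberships - U).max() < 1e-8
    assert np.abs(res.memberships.sum(axis=0) - 1.0).max() < 1e-12


def test_column_sums_conserved_every_iteration(rng):
    X = rng.normal(size=(30, 2))
    w = rng.uniform(size=30)
    seen = []

    def hook(it, U, V):
        seen.append(np.abs(U.sum(axis=0) - w).max())

    cfcm_cluster(X, w, c=3, m=2.0, seed=7, iteration_hook=hook)
    assert seen and max(seen) < 1e-12


def test_objective_trace_non_increasing(rng):
    X = rng.normal(size=(40, 3))
    w = rng.uniform(size=40)
    res = cfcm_cluster(X, w, c=4, m=2.0, seed=3, tol=1e-9)
    trace = np.array(res.objective_trace)
    assert np.all(np.diff(trace) <= 1e-10)
    assert res.converged


def test_centers_inside_support_bounding_box(rng):
    X = rng.uniform(-5, 5, size=(50, 2))
    w = rng.uniform(size=50)
    w[::3] = 0.0
    res = cfcm_cluster(X, w, c=3, m=2.0, seed=2)
    pos = X[w > 0]
    assert np.all(res.centers >= pos.min(axis=0) - 1e-12)
    assert np.all(res.centers <= pos.max(axis=0) + 1e-12)
    # memberships bounded by the context weight
    assert np.all(res.memberships <= w + 1e-12)
    assert np.all(res.memberships >= -1e-15)


def test_deterministic_under_fixed_seed(rng):
    X = rng.normal(size=(25, 2))
    w = rng.uniform(size=25)
    a = cfcm_cluster(X, w, c=3, m=2.0, seed=42)
    b = cfcm_cluster(X, w, c=3, m=2.0, seed=42)
    assert np.array_equal(a.centers, b.centers)
    assert np.array_equal(a.memberships, b.memberships)
    assert a.objective_trace == b.objective_trace


def test_degenerate_weight_and_cluster_errors(rng):
    X = rng.normal(size=(8, 2))
    with pytest.raises(ValueError, match="empty context"):
        cfcm_cluster(X, np.zeros(8), c=2, context_index=4)
    with pytest.raises(ValueError, match="clusters exceed"):
        w = np.zeros(8)
        w[:2] = 0.5
        cfcm_cluster(X, w, c=3)
    with pytest.raises(ValueError, match="m must be > 1"):
        cfcm_cluster(X, np.ones(8), c=2, m=1.0)


def test_coincident_point_gets_full_weight():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
    w = np.array([0.9, 0.7, 0.5])
    init = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
    # centers after first update are the pure points (0,0) and weighted mean of
    # the rest; point 0 coincides with center 0 exactly
    res = cfcm_cluster(X, w, c=2, m=2.0, init=init, max_iter=1)
    assert res.memberships[0, 0] == pytest.approx(0.9)
    assert res.memberships[1, 0] == 0.0


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(min_value=2, max_value=6), st.integers(min_value=0, max_value=10**6))
def test_partition_of_unity_property(p, seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=50)
    cs = make_uniform_contexts(y, p)
    q = rng.uniform(y.min(), y.max(), size=100)
    assert np.abs(cs.memberships(q).sum(axis=0) - 1.0).max() < 1e-12
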