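"""Superimposition geometry: centroid size, rotations, GPA, distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import orthogonal_procrustes

import funnelmorph as fm
from funnelmorph import (
    centroid_size,
    gpa,
    interlandmark_distance,
    mean_shape,
    optimal_rotation,
    procrustes_distance,
)

from conftest import random_rotation


# --------------------------- centroid size ---------------------------------

def test_centroid_size_known_values():
    square = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
    assert centroid_size(square) == pytest.approx(np.sqrt(8))
    two = np.array([[0.0, 0, 0], [2, 0, 0]])
    assert centroid_size(two) == pytest.approx(np.sqrt(2))


def test_centroid_size_homogeneous_and_degenerate(rng):
    x = rng.normal(size=(6, 3))
    assert centroid_size(3.7 * x) == pytest.approx(3.7 * centroid_size(x))
    with pytest.raises(ValueError, match="degenerate"):
        centroid_size(np.ones((4, 3)))


# --------------------------- optimal rotation ------------------------------

def test_optimal_rotation_recovers_known_rotation(rng):
    A = rng.normal(size=(6, 3))
    A -= A.mean(0)
    Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)  # 90 deg about z
    R = optimal_rotation(A, A @ Rz.T)
    np.testing.assert_allclose(A @ R, A @ Rz.T, atol=1e-12)
    np.testing.assert_allclose(optimal_rotation(A, A), np.eye(3), atol=1e-12)


def test_optimal_rotation_matches_scipy_when_proper(rng):
    for _ in range(10):
        A = rng.normal(size=(7, 3))
        B = rng.normal(size=(7, 3))
        A -= A.mean(0)
        B -= B.mean(0)
        R_scipy, _ = orthogonal_procrustes(A, B)
        if np.linalg.det(R_scipy) > 0:
            np.testing.assert_allclose(optimal_rotation(A, B), R_scipy, atol=1e-10)


def test_optimal_rotation_excludes_reflection_brute_force(rng):
    """Mirror-image target: returned proper rotation matches a brute-force
    search over a fine parametrization of SO(3)."""
    from scipy.spatial.transform import Rotation

    A = rng.normal(size=(5, 3))
    A -= A.mean(0)
    B = A.copy()
    B[:, 0] = -B[:, 0]  # reflection of A
    R = optimal_rotation(A, B)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
    resid = np.sum((B - A @ R) ** 2)

    best = np.inf
    # coarse global scan, then refine around the best cell
    grid = Rotation.random(20000, rng=np.random.default_rng(0))
    resids = np.sum((B[None] - np.einsum("kd,nde->nke", A, grid.as_matrix().transpose(0, 2, 1))) ** 2, axis=(1, 2))
    base = grid[int(np.argmin(resids))]
    for _ in range(60):
        local = (Rotation.random(3000, rng=np.random.default_rng(1)).as_rotvec() * 0.02)
        cands = Rotation.from_rotvec(local) * base
        r = np.sum((B[None] - np.einsum("kd,nde->nke", A, cands.as_matrix().transpose(0, 2, 1))) ** 2, axis=(1, 2))
        i = int(np.argmin(r))
        if r[i] < best:
            best = r[i]
            base = cands[i]
    assert resid <= best + 1e-6


# --------------------------------- GPA -------------------------------------

def test_gpa_identical_shapes_collapse(rng):
    base = rng.normal(size=(8, 3))
    stack = []
    for _ in range(6):
        R = random_rotation(rng, 3)
        stack.append(rng.uniform(0.5, 2.0) * base @ R.T + rng.normal(size=3))
    res = gpa(np.array(stack))
    assert res.converged
    for i in range(6):
        for j in range(6):
            assert procrustes_distance(res.aligned[i], res.aligned[j]) < 1e-8


def test_gpa_two_specimen_consensus_equidistant(rng):
    X = rng.normal(size=(2, 10, 3))
    res = gpa(X)
    d1 = procrustes_distance(res.aligned[0], res.consensus)
    d2 = procrustes_distance(res.aligned[1], res.consensus)
    assert d1 == pytest.approx(d2, abs=1e-8)


def test_gpa_consensus_invariants(rng):
    X = rng.normal(size=(12, 9, 3)) + 5.0
    res = gpa(X)
    assert np.abs(res.consensus.mean(axis=0)).max() < 1e-8
    assert np.linalg.norm(res.consensus) == pytest.approx(1.0, abs=1e-8)
    # mean aligned deviation from consensus vanishes after tangent projection
    assert np.abs((res.aligned - res.consensus).sum(axis=0)).max() < 1e-6
    # projection never increases distance to the consensus
    c = res.consensus.ravel()
    for i in range(res.n):
        a = res.aligned[i].ravel()
        pre = a - (1.0 - a @ c) * c  # invert the projection
        assert np.linalg.norm(a - c) <= np.linalg.norm(pre - c) + 1e-8


def test_gpa_global_rotation_invariance(rng):
    X = rng.normal(size=(8, 7, 3))
    res1 = gpa(X)
    Q = random_rotation(rng, 3)
    res2 = gpa(np.einsum("nkd,de->nke", X, Q.T))
    # aligned shapes agree up to one common rotation: all pairwise distances match
    for i in range(8):
        for j in range(i):
            d1 = procrustes_distance(res1.aligned[i], res1.aligned[j])
            d2 = procrustes_distance(res2.aligned[i], res2.aligned[j])
            assert d1 == pytest.approx(d2, abs=1e-8)


def test_gpa_centroid_sizes_are_preserved_raw_sizes(rng):
    X = rng.normal(size=(4, 6, 3))
    res = gpa(X)
    for i in range(4):
        assert res.centroid_sizes[i] == pytest.approx(centroid_size(X[i]))
    np.testing.assert_allclose(res.log_centroid_sizes, np.log(res.centroid_sizes))


def test_gpa_nonconvergence_warns():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(6, 5, 3))
    with pytest.warns(RuntimeWarning, match="did not converge"):
        res = gpa(X, max_iter=1)
    assert not res.converged


# ------------------------------ distances ----------------------------------

def test_procrustes_distance_oracle(rng):
    s1 = rng.normal(size=(3, 2))
    s2 = rng.normal(size=(3, 2))
    oracle = np.sqrt(sum((s1[i, j] - s2[i, j]) ** 2 for i in range(3) for j in range(2)))
    assert procrustes_distance(s1, s2) == pytest.approx(oracle, abs=1e-12)
    assert procrustes_distance(s1, s1) == 0.0
    assert procrustes_distance(s1, s2) == procrustes_distance(s2, s1)
    with pytest.raises(ValueError, match="mismatch"):
        procrustes_distance(s1, rng.normal(size=(4, 2)))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.integers(0, 2**32 - 1))
def test_procrustes_distance_triangle_inequality(seed):
    r = np.random.default_rng(seed)
    a, b, c = r.normal(size=(3, 5, 3))
    assert procrustes_distance(a, c) <= (
        procrustes_distance(a, b) + procrustes_distance(b, c) + 1e-12
    )


def test_interlandmark_distance():
    cfg = fm.LandmarkConfiguration(
        "s", np.array([[0.0, 0, 0], [3, 4, 0], [1, 1, 1]]), ("a", "b", "c")
    )
    assert interlandmark_distance(cfg, "a", "b") == pytest.approx(5.0)
    assert interlandmark_distance(cfg, "a", "a") == 0.0
    with pytest.raises(KeyError, match="available"):
        interlandmark_distance(cfg, "a", "nope")


def test_interlandmark_distance_rigid_invariance(rng):
    coords = rng.normal(size=(4, 3))
    names = ("a", "b", "c", "d")
    base = fm.LandmarkConfiguration("s", coords, names)
    R = random_rotation(rng, 3)
    moved = fm.LandmarkConfiguration("s", coords @ R.T + rng.normal(size=3), names)
    assert interlandmark_distance(moved, "a", "c") == pytest.approx(
        interlandmark_distance(base, "a", "c")
    )


def test_mean_shape(rng):
    s = rng.normal(size=(4, 3))
    np.testing.assert_array_equal(mean_shape([s]), s)
    t = rng.normal(size=(4, 3))
    np.testing.assert_allclose(mean_shape([s, t]), (s + t) / 2)
    np.testing.assert_allclose(mean_shape([s, -s]), np.zeros((4, 3)), atol=1e-15)
    with pytest.raises(ValueError, match="empty"):
        mean_shape(np.empty((0, 4, 3)))
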