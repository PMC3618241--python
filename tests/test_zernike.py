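"""Descriptor computation: basis, moments, invariants, and their symmetries."""

import numpy as np
import pytest

from zdsearch import (
    EmptySupportError,
    IndexConstraintError,
    ParameterError,
    VoxelGrid,
    compute_descriptor,
    compute_moments,
    descriptor_length,
    generate_toy_grid,
    invariants,
    normalize_grid,
    zernike_basis,
)
from zdsearch.zernike import ZernikeMoments, nl_pairs


def rotations24(values):
    """All 24 proper lattice rotations of a cubic array."""

    def spins(a):
        for k in range(4):
            yield np.rot90(a, k, (0, 1))

    yield from spins(values)
    for axes_k in [(2, (0, 2)), (1, (0, 2)), (3, (0, 2)), (1, (1, 2)), (3, (1, 2))]:
        yield from spins(np.rot90(values, axes_k[0], axes_k[1]))


# ------------------------------------------------------------ descriptor_length


@pytest.mark.parametrize("order,expected", [(0, 1), (1, 2), (2, 4), (20, 121)])
def test_descriptor_length_counts_valid_nl_pairs(order, expected):
    # independent enumeration oracle
    brute = sum(
        1 for n in range(order + 1) for l in range(n + 1) if (n - l) % 2 == 0
    )
    assert brute == expected
    assert descriptor_length(order) == expected


def test_descriptor_length_rejects_negative_order():
    with pytest.raises(ParameterError):
        descriptor_length(-1)


# ------------------------------------------------------------------------ basis


def test_l0_basis_is_isotropic():
    rng = np.random.default_rng(0)
    dirs = rng.normal(size=(20, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    vals = zernike_basis(2, 0, 0, 0.5 * dirs)
    assert np.allclose(vals, vals[0])


def test_basis_conjugate_symmetry():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(30, 3))
    pts *= (rng.uniform(0, 1, size=30) / np.linalg.norm(pts, axis=1))[:, None]
    for n, l, m in [(4, 2, 1), (5, 3, 2), (6, 6, 5)]:
        a = zernike_basis(n, l, -m, pts)
        b = (-1) ** m * np.conj(zernike_basis(n, l, m, pts))
        assert np.allclose(a, b)


@pytest.mark.parametrize("triple", [(1, 0, 0), (2, 1, 0), (3, 3, 4), (2, 3, 0)])
def test_basis_rejects_invalid_triples(triple):
    with pytest.raises(IndexConstraintError):
        zernike_basis(*triple, np.zeros(3))


def test_basis_orthonormality_by_quadrature():
    """Gram matrix of all order-<=4 basis functions is the identity."""
    N = 48
    ax = (np.arange(N) + 0.5) / N * 2 - 1
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xx, yy, zz], -1).reshape(-1, 3)
    pts = pts[np.linalg.norm(pts, axis=1) <= 1]
    dV = (2 / N) ** 3
    triples = [(n, l, m) for n, l in nl_pairs(4) for m in range(-l, l + 1)]
    B = np.stack([zernike_basis(n, l, m, pts) for (n, l, m) in triples])
    gram = (B * dV) @ np.conj(B.T)
    assert np.abs(gram - np.eye(len(triples))).max() < 0.02


# -------------------------------------------------------------- normalize_grid


def test_normalize_single_voxel_maps_to_origin():
    vals = np.zeros((9, 9, 9))
    vals[4, 4, 4] = 1.0
    g = normalize_grid(VoxelGrid(values=vals))
    pts, _ = g.support_points()
    assert np.allclose(pts, 0.0)


def test_normalize_symmetric_pair_is_balanced():
    vals = np.zeros((9, 9, 9))
    vals[2, 4, 4] = 1.0
    vals[6, 4, 4] = 1.0
    g = normalize_grid(VoxelGrid(values=vals), margin=0.7)
    pts, _ = g.support_points()
    radii = np.linalg.norm(pts, axis=1)
    assert np.allclose(pts.mean(axis=0), 0.0)
    assert np.allclose(radii, [0.7, 0.7])


def test_normalize_bounds_support_radius():
    g = normalize_grid(VoxelGrid(values=np.random.default_rng(0).uniform(size=(12, 12, 12))))
    pts, _ = g.support_points()
    assert np.linalg.norm(pts, axis=1).max() <= 0.7 + 1e-12


def test_normalize_rejects_empty_grid():
    with pytest.raises(EmptySupportError):
        normalize_grid(VoxelGrid(values=np.zeros((4, 4, 4))))


# -------------------------------------------------------------------- moments


def test_zero_field_gives_zero_moments_and_invariants():
    grid = VoxelGrid(values=np.zeros((8, 8, 8)))
    mom = compute_moments(grid, order=4)
    assert all(v == 0 for v in mom.entries.values())
    assert np.all(invariants(mom).values == 0)


def test_moments_are_linear_in_field():
    g = generate_toy_grid("ellipsoid", N=16)
    g1 = normalize_grid(g)
    g2 = VoxelGrid(values=2 * g1.values, spacing=g1.spacing, origin=g1.origin)
    m1 = compute_moments(g1, order=4)
    m2 = compute_moments(g2, order=4)
    for key, v in m1.entries.items():
        assert m2.entries[key] == pytest.approx(2 * v, abs=1e-12)


def test_spherical_input_suppresses_l_gt0():
    d = compute_descriptor(generate_toy_grid("sphere", N=32), order=8)
    pairs = nl_pairs(8)
    l0 = max(v for (n, l), v in zip(pairs, d.values) if l == 0)
    lg = max(v for (n, l), v in zip(pairs, d.values) if l > 0)
    assert lg < 0.02 * l0


# ------------------------------------------------------------------ invariants


def test_single_real_moment_yields_its_magnitude():
    mom = ZernikeMoments(order=2)
    for n, l in nl_pairs(2):
        for m in range(-l, l + 1):
            mom.entries[(n, l, m)] = 0j
    mom.entries[(2, 2, 0)] = -1.5 + 0j
    vec = invariants(mom)
    pos = nl_pairs(2).index((2, 2))
    expected = np.zeros(4)
    expected[pos] = 1.5
    assert np.allclose(vec.values, expected)


def test_descriptor_rotation_invariance_small_grid():
    g = generate_toy_grid("two_spheres", N=24)
    ref = compute_descriptor(g, order=6).values
    for rot in rotations24(g.values):
        d = compute_descriptor(VoxelGrid(values=rot.copy()), order=6).values
        assert np.abs(d - ref).max() / np.abs(ref).max() < 1e-6


def test_descriptor_homogeneity_under_scaling():
    g = generate_toy_grid("cube", N=16)
    ref = compute_descriptor(g, order=6).values
    scaled = compute_descriptor(VoxelGrid(values=3.25 * g.values), order=6).values
    assert np.abs(scaled - 3.25 * ref).max() / np.abs(ref).max() < 1e-12


def test_descriptor_is_nonnegative_with_contract_length():
    d = compute_descriptor(generate_toy_grid("ellipsoid", N=16), order=10)
    assert len(d.values) == descriptor_length(10)
    assert np.all(d.values >= 0)
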