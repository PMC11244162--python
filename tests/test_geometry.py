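"""Thinning and normal estimation against analytic oracles."""

import numpy as np
import pytest
from scipy.ndimage import convolve

from envquant import PhantomSpec, estimate_normals, generate_phantom, thin, trace_curves
from envquant.geometry import canonical_rotation, rotate_points, rotate_vectors

from conftest import concentric_labels

_K8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(skel):
    return convolve(skel.astype(np.uint8), _K8, mode="constant")[skel]


def test_thin_ring_gives_closed_single_pixel_curve():
    ring = concentric_labels(size=201, r_inner=70.0) == 1
    skel = thin(ring)
    counts = _neighbor_counts(skel)
    assert (counts == 2).all()  # every pixel exactly two curve neighbors
    assert skel.sum() < ring.sum()
    assert not (skel & ~ring).any()  # support never grows


def test_thin_idempotent_and_empty():
    ring = concentric_labels(size=151, r_inner=40.0) == 1
    skel = thin(ring)
    assert np.array_equal(thin(skel), skel)
    empty = np.zeros((10, 10), dtype=bool)
    assert not thin(empty).any()


def test_thin_point_count_matches_analytic_perimeter():
    """Curve pixel count within 10% of the analytic perimeter / pixel size."""
    spec = PhantomSpec(n_slices=1, jitter_sd=0.0, seed=13)
    stack, truth = generate_phantom(spec)
    skel = thin(stack.masks[0] == 2)
    r = (truth.inner_radius_profile + truth.separation_profile) / spec.pixel_size
    dr = np.gradient(r, truth.theta)
    perimeter = np.trapezoid(np.sqrt(r**2 + dr**2), truth.theta)
    assert abs(skel.sum() - perimeter) / perimeter < 0.10


def test_rot90_equivariance_of_thin():
    spec = PhantomSpec(n_slices=1, seed=14)
    stack, _ = generate_phantom(spec)
    mask = stack.masks[0] == 1
    skel = thin(mask)
    for k in (1, 2, 3):
        assert np.array_equal(thin(np.rot90(mask, k)), np.rot90(skel, k))


def test_trace_closed_curve_ordering():
    skel = thin(concentric_labels(size=201, r_inner=60.0) == 1)
    cs = trace_curves(skel)
    assert len(cs.curves) == 1 and cs.closed[0]
    coords = cs.curves[0]
    assert len(coords) == skel.sum()
    steps = np.abs(np.diff(coords, axis=0)).max(axis=1)
    assert (steps == 1).all()  # consecutive pixels are 8-neighbors


def test_circle_normals_radial_within_3_degrees():
    center = 100.0
    skel = thin(concentric_labels(size=201, r_inner=50.0) == 1)
    origins, normals, n_skipped = estimate_normals(skel)
    radial = origins - center
    radial = radial / np.linalg.norm(radial, axis=1, keepdims=True)
    ang = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", normals, radial), -1, 1)))
    assert ang.max() < 3.0
    assert n_skipped == 0
    assert np.allclose(np.linalg.norm(normals, axis=1), 1.0, atol=1e-9)


def test_straight_segment_normals_point_away_from_interior():
    """Horizontal membrane with the interior below: all normals point up (-row)."""
    mask = np.zeros((41, 61), dtype=bool)
    mask[20, 5:56] = True
    interior = np.zeros_like(mask)
    interior[30, 25:35] = True
    origins, normals, _ = estimate_normals(mask, interior_reference=interior)
    keep = (origins[:, 1] > 8) & (origins[:, 1] < 52)  # away from open ends
    assert np.allclose(normals[keep], [-1.0, 0.0], atol=1e-9)


def test_star_phantom_normals_vs_analytic():
    """Mean angular error against the analytic normal of r(theta) below 5 deg."""
    spec = PhantomSpec(n_slices=1, jitter_sd=0.0, seed=3)
    stack, truth = generate_phantom(spec)
    inner = stack.masks[0] == 1
    origins, normals, _ = estimate_normals(thin(inner), interior_reference=inner)
    c = (spec.image_size - 1) / 2.0
    th = np.arctan2(origins[:, 0] - c, origins[:, 1] - c) % (2 * np.pi)
    r = np.interp(th, truth.theta, truth.inner_radius_profile, period=2 * np.pi)
    drdth = np.interp(th, truth.theta, np.gradient(truth.inner_radius_profile, truth.theta),
                      period=2 * np.pi)
    tx = drdth * np.cos(th) - r * np.sin(th)
    ty = drdth * np.sin(th) + r * np.cos(th)
    na = np.column_stack([-tx, ty])  # (row, col) outward candidate
    sign = np.einsum("ij,ij->i", na, np.column_stack([np.sin(th), np.cos(th)]))
    na[sign < 0] *= -1
    na /= np.linalg.norm(na, axis=1, keepdims=True)
    ang = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", normals, na), -1, 1)))
    assert ang.mean() < 5.0


def test_normal_field_winding_number_one():
    """Normals on a closed convex curve rotate exactly once around the cell."""
    skel = thin(concentric_labels(size=201, r_inner=55.0) == 1)
    cs = trace_curves(skel)
    origins, normals, _ = estimate_normals(skel)
    order = {tuple(p): i for i, p in enumerate(cs.curves[0])}
    idx = np.array([order[tuple(p)] for p in origins])
    ang = np.arctan2(normals[:, 0], normals[:, 1])[np.argsort(idx)]
    winding = np.sum((np.diff(ang) + np.pi) % (2 * np.pi) - np.pi) / (2 * np.pi)
    assert abs(abs(winding) - 1.0) < 0.05


def test_estimate_normals_rot90_equivariant_exactly():
    spec = PhantomSpec(n_slices=1, seed=15)
    stack, _ = generate_phantom(spec)
    inner = stack.masks[0] == 1
    skel = thin(inner)
    origins, normals, _ = estimate_normals(skel, interior_reference=inner)
    for k in (1, 2, 3):
        ok, nk, _ = estimate_normals(np.rot90(skel, k), interior_reference=np.rot90(inner, k))
        o_exp = rotate_points(origins, k, skel.shape).astype(int)
        n_exp = rotate_vectors(normals, k)
        perm = np.lexsort((ok[:, 1], ok[:, 0]))
        perm_exp = np.lexsort((o_exp[:, 1], o_exp[:, 0]))
        assert np.array_equal(ok[perm], o_exp[perm_exp])
        assert np.array_equal(nk[perm], n_exp[perm_exp])


def test_canonical_rotation_consistency():
    rng = np.random.default_rng(0)
    mask = rng.random((17, 17)) > 0.7
    k0 = canonical_rotation(mask)
    canon = np.rot90(mask, k0)
    for m in (1, 2, 3):
        km = canonical_rotation(np.rot90(mask, m))
        assert np.array_equal(np.rot90(np.rot90(mask, m), km), canon)


def test_isolated_pixels_are_skipped():
    mask = np.zeros((20, 20), dtype=bool)
    mask[5, 5] = True
    origins, normals, n_skipped = estimate_normals(mask)
    assert len(origins) == 0 and n_skipped == 1
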