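"""Skeletonization of membrane masks and outward normal estimation.

Segmentation masks are thinned to single-pixel-thick 8-connected curves by
iterative homotopic thinning (``skimage.morphology.thin``), the standard
equivalent of MATLAB's ``bwmorph(mask, 'thin', Inf)``.  On the thinned inner
membrane, an extracellular-facing unit normal is computed at every curve
pixel from the principal direction (total-least-squares line fit) of the
curve pixels within an along-curve distance of ``neighborhood`` pixels.

Orientation canonicalization
----------------------------
Pixel-level thinning templates are not symmetric under 90-degree image
rotations, yet the tomogram's in-plane axes are arbitrary, so reported
statistics must not depend on them.  Both :func:`thin` and
:func:`estimate_normals` therefore rotate their input to a canonical
orientation (the lexicographically smallest of the four 90-degree rotations
of the mask bytes), operate there, and map the result back.  Rotating pixel
coordinates and unit vectors by multiples of 90 degrees is exact, so the
whole operation is exactly equivariant under image rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve
from skimage.morphology import thin as _sk_thin

_NEIGH_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def canonical_rotation(mask: np.ndarray) -> int:
    """Number of CCW quarter turns putting ``mask`` in canonical orientation.

    The canonical orientation is the rotation whose packed bytes compare
    smallest; ties (rotationally symmetric masks) break toward the smallest
    number of turns.
    """
    mask = np.ascontiguousarray(mask.astype(bool))
    best_k, best_bytes = 0, np.packbits(mask).tobytes()
    for k in (1, 2, 3):
        b = np.packbits(np.ascontiguousarray(np.rot90(mask, k))).tobytes()
        if b < best_bytes:
            best_k, best_bytes = k, b
    return best_k


def rotate_points(points: np.ndarray, k: int, shape: tuple) -> np.ndarray:
    """Map (row, col) points through ``np.rot90(a, k)``; exact for integers."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    H, W = shape[:2]
    k = k % 4
    if k == 0:
        out = pts.copy()
    elif k == 1:  # out[i, j] = a[j, W-1-i]  ->  (r, c) -> (W-1-c, r)
        out = np.column_stack([W - 1 - pts[:, 1], pts[:, 0]])
    elif k == 2:
        out = np.column_stack([H - 1 - pts[:, 0], W - 1 - pts[:, 1]])
    else:
        out = np.column_stack([pts[:, 1], H - 1 - pts[:, 0]])
    return out


def rotate_vectors(vectors: np.ndarray, k: int) -> np.ndarray:
    """Rotate (dr, dc) direction vectors by ``k`` CCW quarter turns; exact."""
    v = np.asarray(vectors, dtype=float).reshape(-1, 2)
    k = k % 4
    if k == 0:
        return v.copy()
    if k == 1:
        return np.column_stack([-v[:, 1], v[:, 0]])
    if k == 2:
        return -v
    return np.column_stack([v[:, 1], -v[:, 0]])


def thin(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to single-pixel 8-connected curves.

    Iterated to convergence; idempotent; never adds pixels outside the
    input's support; closed contours stay closed.  Exactly equivariant under
    90-degree rotations (see module docstring).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("thin expects a 2D mask")
    if not mask.any():
        return mask.copy()
    k = canonical_rotation(mask)
    out = _sk_thin(np.ascontiguousarray(np.rot90(mask, k)))
    return np.ascontiguousarray(np.rot90(out, -k))


@dataclass
class CurveSet:
    """Ordered single-pixel curves traced from a thinned mask.

    ``curves`` holds (m, 2) integer arrays of (row, col) pixels in traversal
    order; ``closed[i]`` marks cycles.  Pixels with three or more neighbors
    (junctions) are excluded from curves and reported separately.
    """

    curves: list = field(default_factory=list)
    closed: list = field(default_factory=list)
    junction_pixels: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    shape: tuple = (0, 0)

    @property
    def n_pixels(self) -> int:
        return sum(len(c) for c in self.curves)


def trace_curves(skeleton: np.ndarray) -> CurveSet:
    """Order the pixels of a thinned mask into open or closed curves."""
    skeleton = np.asarray(skeleton, dtype=bool)
    counts = convolve(skeleton.astype(np.uint8), _NEIGH_KERNEL, mode="constant")
    junctions = skeleton & (counts >= 3)
    simple = skeleton & ~junctions

    coords = {tuple(p) for p in np.argwhere(simple)}
    neigh = {}
    for p in coords:
        neigh[p] = [q for q in ((p[0] + dr, p[1] + dc) for dr, dc in _OFFSETS8) if q in coords]

    cs = CurveSet(shape=skeleton.shape, junction_pixels=np.argwhere(junctions))
    visited = set()
    # endpoints first so open segments are traced end-to-end, then cycles
    order = sorted(coords, key=lambda p: (len(neigh[p]) != 1, p))
    for start in order:
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        prev = None
        cur = start
        while True:
            nxt = [q for q in neigh[cur] if q != prev and q not in visited]
            if not nxt:
                break
            # prefer 4-connected continuation to avoid corner-cutting on
            # staircase curves where a pixel touches two path pixels
            nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
            prev, cur = cur, nxt[0]
            path.append(cur)
            visited.add(cur)
        is_closed = len(path) > 2 and cur in ((start[0] + dr, start[1] + dc) for dr, dc in _OFFSETS8)
        cs.curves.append(np.array(path, dtype=int))
        cs.closed.append(bool(is_closed))
    return cs


def _principal_directions(windows: np.ndarray) -> np.ndarray:
    """Unit principal axis of each (w, 2) coordinate window, vectorized."""
    d = windows - windows.mean(axis=1, keepdims=True)
    a = np.einsum("ij,ij->i", d[:, :, 0], d[:, :, 0])
    b = np.einsum("ij,ij->i", d[:, :, 0], d[:, :, 1])
    c = np.einsum("ij,ij->i", d[:, :, 1], d[:, :, 1])
    lam = 0.5 * ((a + c) + np.sqrt((a - c) ** 2 + 4.0 * b * b))
    v1 = np.column_stack([b, lam - a])
    v2 = np.column_stack([lam - c, b])
    n1 = np.einsum("ij,ij->i", v1, v1)
    n2 = np.einsum("ij,ij->i", v2, v2)
    v = np.where((n1 >= n2)[:, None], v1, v2)
    norm = np.sqrt(np.einsum("ij,ij->i", v, v))
    norm[norm == 0] = 1.0
    return v / norm[:, None]


def _normals_for_curve(coords: np.ndarray, closed: bool, neighborhood: int) -> np.ndarray:
    m = len(coords)
    offs = np.arange(-neighborhood, neighborhood + 1)
    idx = np.arange(m)[:, None] + offs[None, :]
    if closed:
        idx %= m
    else:
        idx = np.clip(idx, 0, m - 1)
    tangents = _principal_directions(coords[idx].astype(float))
    # rotate tangent by 90 deg; outward sign fixed later
    return np.column_stack([-tangents[:, 1], tangents[:, 0]])


def estimate_normals(
    skeleton: np.ndarray,
    interior_reference: np.ndarray | None = None,
    neighborhood: int = 10,
):
    """Outward unit normals at every pixel of a thinned inner-membrane curve.

    Parameters
    ----------
    skeleton
        Thinned (single-pixel) binary inner-membrane mask.
    interior_reference
        Binary mask whose centroid defines "inside" (typically the un-thinned
        inner-membrane mask); defaults to the skeleton itself.
    neighborhood
        Along-curve half-window (in pixels) for the tangent fit.  The
        along-curve metric keeps opposite cell walls from contaminating the
        tangent at narrow necks.

    Returns
    -------
    origins : (N, 2) int array of curve pixels (row, col)
    normals : (N, 2) float array of outward unit vectors (|n| = 1)
    n_skipped : pixels excluded (junctions, isolated pixels, degenerate sign)
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        raise ValueError("empty skeleton: no inner-membrane pixels")
    ref = skeleton if interior_reference is None else np.asarray(interior_reference, dtype=bool)

    k = canonical_rotation(skeleton)
    skel_c = np.ascontiguousarray(np.rot90(skeleton, k))
    ref_c = np.ascontiguousarray(np.rot90(ref, k))
    centroid = np.argwhere(ref_c).mean(axis=0)

    cs = trace_curves(skel_c)
    n_skipped = len(cs.junction_pixels)
    origins, normals = [], []
    for coords, closed in zip(cs.curves, cs.closed):
        if len(coords) < 3:
            n_skipped += len(coords)
            continue
        nrm = _normals_for_curve(coords, closed, neighborhood)
        outward = np.einsum("ij,ij->i", nrm, coords - centroid[None, :])
        flip = outward < 0
        nrm[flip] = -nrm[flip]
        degenerate = outward == 0
        if degenerate.any():
            n_skipped += int(degenerate.sum())
            coords, nrm = coords[~degenerate], nrm[~degenerate]
        origins.append(coords)
        normals.append(nrm)

    if not origins:
        return np.empty((0, 2), dtype=int), np.empty((0, 2)), n_skipped
    origins = np.concatenate(origins)
    normals = np.concatenate(normals)
    origins = rotate_points(origins, -k, skel_c.shape).astype(int)
    normals = rotate_vectors(normals, -k)
    return origins, normals, n_skipped
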