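"""Normal-vector ray casting against S-layer and outer-membrane curves.

From every inner-membrane curve pixel, a single-pixel ray is cast along the
outward normal to score S-layer presence/absence, and a three-pixel-thick ray
(the ray plus two parallel lines offset +/-1 px perpendicular) is cast
against the outer membrane to measure the intermembrane separation.  The
thick-ray distance is the mean Euclidean distance from the origin to every
outer-membrane pixel intersected; measurements touching more than
``max_hit_pixels`` (default 4) outer-membrane pixels are deemed noisy and
discarded, and rays that intersect no outer-membrane pixel are discarded as
no-hits.

Rays are traversed with a supercover line walk (every pixel the continuous
line passes through, with both pixels taken at exact corner crossings), so a
thin ray cannot tunnel diagonally through an 8-connected single-pixel curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import geometry
from .io import SegmentationStack, binarize, largest_component

logger = logging.getLogger(__name__)

# discard_reason codes
OK = 0
TOO_MANY_HITS = 1
NO_HIT = 2

_REASONS = {OK: "", TOO_MANY_HITS: "too_many_hits", NO_HIT: "no_hit"}


@dataclass(frozen=True)
class MeasureParams:
    """Tunable parameters of the per-cell measurement."""

    neighborhood: int = 10          # along-curve half-window for normals, px
    max_ray_length_nm: float = 100.0
    max_hit_pixels: int = 4         # thick-ray discard rule
    clean_components: bool = True   # keep largest component per structure/slice
    slab_slices: int = 50


@dataclass
class RayHit:
    """Outcome of casting one ray against one target structure."""

    origin: tuple
    direction: tuple
    structure: str
    hit_pixels: np.ndarray
    distance_px: float      # nan when no hit / invalid
    valid: bool
    truncated: bool = False


@dataclass
class CellMeasurements:
    """Per-cell record of S-layer hits and valid intermembrane distances.

    One entry per processed ray in each of the per-ray arrays.  Counters
    satisfy the conservation law
    ``n_rays + n_skipped_pixels == inner-membrane curve pixels`` and, per
    structure, hits + misses (S-layer) and valid + discarded + no-hit
    (outer membrane) each equal ``n_rays``.
    """

    cell_id: str
    pixel_size: float
    timepoint_label: str = ""
    is_control: bool = False
    slice_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    origin_row: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    origin_col: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    slayer_hit: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    slayer_distance_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    om_distance_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    om_n_hits: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    om_valid: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    discard_reason: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n_skipped_pixels: int = 0
    n_skipped_slices: int = 0

    @property
    def n_rays(self) -> int:
        return len(self.slayer_hit)

    @property
    def valid_distances_nm(self) -> np.ndarray:
        return self.om_distance_nm[self.om_valid]

    def counters(self) -> dict:
        return {
            "n_rays": self.n_rays,
            "n_skipped_pixels": self.n_skipped_pixels,
            "n_skipped_slices": self.n_skipped_slices,
            "slayer_hits": int(self.slayer_hit.sum()),
            "slayer_misses": int((~self.slayer_hit).sum()),
            "om_valid": int(self.om_valid.sum()),
            "om_too_many_hits": int((self.discard_reason == TOO_MANY_HITS).sum()),
            "om_no_hit": int((self.discard_reason == NO_HIT).sum()),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "slice": self.slice_index,
                "origin_row": self.origin_row,
                "origin_col": self.origin_col,
                "slayer_hit": self.slayer_hit,
                "om_distance_nm": np.where(self.om_valid, self.om_distance_nm, np.nan),
                "valid": self.om_valid,
                "discard_reason": [_REASONS[r] for r in self.discard_reason],
            }
        )


@njit(cache=True)
def _walk(r0, c0, dr, dc, max_len, mask, stop_first, out_r, out_c, out_n):
    """Supercover traversal from (r0, c0) along (dr, dc) up to max_len.

    Records pixels of ``mask`` that the line passes through (entry parameter
    t <= max_len).  At an exact corner crossing both side pixels are visited,
    then the diagonal step is taken, so the traversal is 4-connected and
    axis-symmetric.  Returns (n_hits, truncated).
    """
    H, W = mask.shape
    ir = int(np.floor(r0 + 0.5))
    ic = int(np.floor(c0 + 0.5))
    step_r = 1 if dr > 0 else (-1 if dr < 0 else 0)
    step_c = 1 if dc > 0 else (-1 if dc < 0 else 0)
    inf = 1.0e30
    if dr > 0:
        t_max_r = ((ir + 0.5) - r0) / dr
        t_del_r = 1.0 / dr
    elif dr < 0:
        t_max_r = (r0 - (ir - 0.5)) / (-dr)
        t_del_r = 1.0 / (-dr)
    else:
        t_max_r = inf
        t_del_r = inf
    if dc > 0:
        t_max_c = ((ic + 0.5) - c0) / dc
        t_del_c = 1.0 / dc
    elif dc < 0:
        t_max_c = (c0 - (ic - 0.5)) / (-dc)
        t_del_c = 1.0 / (-dc)
    else:
        t_max_c = inf
        t_del_c = inf

    n = 0
    t = 0.0
    truncated = False
    while t <= max_len:
        if ir < 0 or ir >= H or ic < 0 or ic >= W:
            truncated = True
            break
        if mask[ir, ic]:
            if n < out_n:
                out_r[n] = ir
                out_c[n] = ic
            n += 1
            if stop_first:
                break
        if t_max_r < t_max_c:
            t = t_max_r
            ir += step_r
            t_max_r += t_del_r
        elif t_max_c < t_max_r:
            t = t_max_c
            ic += step_c
            t_max_c += t_del_c
        else:
            # exact corner: supercover visits both side pixels
            t = t_max_r
            if t <= max_len:
                rr = ir + step_r
                if 0 <= rr < H and 0 <= ic < W and mask[rr, ic]:
                    if n < out_n:
                        out_r[n] = rr
                        out_c[n] = ic
                    n += 1
                cc = ic + step_c
                if 0 <= ir < H and 0 <= cc < W and mask[ir, cc]:
                    if n < out_n:
                        out_r[n] = ir
                        out_c[n] = cc
                    n += 1
                if stop_first and n > 0:
                    break
            ir += step_r
            ic += step_c
            t_max_r += t_del_r
            t_max_c += t_del_c
    return n, truncated


@njit(cache=True)
def _measure_rays(origins, normals, slayer_mask, outer_mask, max_len, max_hits):
    """Batched thin cast (S-layer) + thick cast (outer membrane) per ray.

    Returns per-ray arrays: slayer_hit, slayer_dist_px, om_dist_px,
    om_n_hits, om_reason (0 ok / 1 too many hits / 2 no hit).
    """
    n_rays = origins.shape[0]
    slayer_hit = np.zeros(n_rays, dtype=np.bool_)
    slayer_dist = np.full(n_rays, np.nan)
    om_dist = np.full(n_rays, np.nan)
    om_n = np.zeros(n_rays, dtype=np.int64)
    om_reason = np.zeros(n_rays, dtype=np.int64)

    cap = 256
    buf_r = np.empty(cap, dtype=np.int64)
    buf_c = np.empty(cap, dtype=np.int64)
    hit_r = np.empty(3 * cap, dtype=np.int64)
    hit_c = np.empty(3 * cap, dtype=np.int64)
    dists = np.empty(3 * cap)

    for i in range(n_rays):
        r0 = float(origins[i, 0])
        c0 = float(origins[i, 1])
        dr = normals[i, 0]
        dc = normals[i, 1]

        # thin ray against the S-layer: presence/absence + first-hit distance
        n, _ = _walk(r0, c0, dr, dc, max_len, slayer_mask, True, buf_r, buf_c, cap)
        if n > 0:
            slayer_hit[i] = True
            slayer_dist[i] = np.sqrt((buf_r[0] - r0) ** 2 + (buf_c[0] - c0) ** 2)

        # 3-px-thick ray against the outer membrane: centre + two offsets
        m = 0
        for off in (-1.0, 0.0, 1.0):
            orr = r0 - off * dc
            occ = c0 + off * dr
            n, _ = _walk(orr, occ, dr, dc, max_len, outer_mask, False, buf_r, buf_c, cap)
            for j in range(min(n, cap)):
                dup = False
                for q in range(m):
                    if hit_r[q] == buf_r[j] and hit_c[q] == buf_c[j]:
                        dup = True
                        break
                if not dup and m < 3 * cap:
                    hit_r[m] = buf_r[j]
                    hit_c[m] = buf_c[j]
                    m += 1
        om_n[i] = m
        if m == 0:
            om_reason[i] = 2
        elif m > max_hits:
            om_reason[i] = 1
        else:
            for j in range(m):
                dists[j] = np.sqrt((hit_r[j] - r0) ** 2 + (hit_c[j] - c0) ** 2)
            # sort so the mean is independent of traversal order
            for a in range(1, m):
                key = dists[a]
                b = a - 1
                while b >= 0 and dists[b] > key:
                    dists[b + 1] = dists[b]
                    b -= 1
                dists[b + 1] = key
            s = 0.0
            for j in range(m):
                s += dists[j]
            om_dist[i] = s / m
    return slayer_hit, slayer_dist, om_dist, om_n, om_reason


def _as_unit(direction) -> np.ndarray:
    d = np.asarray(direction, dtype=float)
    n = np.hypot(d[0], d[1])
    if n == 0:
        raise ValueError("zero-length ray direction")
    return d / n


def cast_thin(origin, direction, target_mask, max_length_px: float) -> RayHit:
    """Cast a single-pixel ray; hit = first target pixel on the line."""
    d = _as_unit(direction)
    mask = np.ascontiguousarray(target_mask, dtype=bool)
    buf_r = np.empty(8, dtype=np.int64)
    buf_c = np.empty(8, dtype=np.int64)
    n, truncated = _walk(
        float(origin[0]), float(origin[1]), d[0], d[1], float(max_length_px), mask, True, buf_r, buf_c, 8
    )
    if n > 0:
        pix = np.array([[buf_r[0], buf_c[0]]])
        dist = float(np.hypot(buf_r[0] - origin[0], buf_c[0] - origin[1]))
        return RayHit(tuple(origin), tuple(d), "slayer", pix, dist, True, truncated)
    return RayHit(tuple(origin), tuple(d), "slayer", np.empty((0, 2), dtype=int), np.nan, False, truncated)


def cast_thick(origin, direction, outer_mask, max_length_px: float, max_hit_pixels: int = 4) -> RayHit:
    """Cast a 3-px-thick ray; distance = mean over hit pixels; >4 hits discarded."""
    d = _as_unit(direction)
    mask = np.ascontiguousarray(outer_mask, dtype=bool)
    origins = np.array([[float(origin[0]), float(origin[1])]])
    normals = np.array([[d[0], d[1]]])
    sl_dummy = np.zeros_like(mask)
    _, _, om_dist, om_n, om_reason = _measure_rays(
        origins, normals, sl_dummy, mask, float(max_length_px), max_hit_pixels
    )
    # recover hit pixels for reporting
    cap = 256
    buf_r = np.empty(cap, dtype=np.int64)
    buf_c = np.empty(cap, dtype=np.int64)
    pix = []
    for off in (-1.0, 0.0, 1.0):
        n, _ = _walk(
            float(origin[0]) - off * d[1], float(origin[1]) + off * d[0],
            d[0], d[1], float(max_length_px), mask, False, buf_r, buf_c, cap,
        )
        pix.extend(zip(buf_r[:n].tolist(), buf_c[:n].tolist()))
    pix = np.array(sorted(set(pix)), dtype=int).reshape(-1, 2)
    valid = om_reason[0] == OK
    return RayHit(tuple(origin), tuple(d), "outer", pix, float(om_dist[0]), bool(valid))


def measure_slice(labels2d, pixel_size: float, params: MeasureParams):
    """Thin all structures in one slice, estimate normals, cast all rays.

    The slice is processed in its canonical orientation (see
    :mod:`envquant.geometry`) and per-ray origins are mapped back, so every
    reported quantity is exactly invariant under 90-degree rotations of the
    input slice.

    Returns a dict of per-ray arrays plus counters, or None when the slice
    has no inner membrane.
    """
    from .io import STRUCTURES

    labels2d = np.asarray(labels2d)
    masks = {}
    for name, lbl in STRUCTURES.items():
        m = labels2d == lbl
        if params.clean_components and name != "slayer" and m.any():
            m = largest_component(m)
        masks[name] = m
    if not masks["inner"].any():
        return None

    k = geometry.canonical_rotation(masks["inner"])
    shape_c = np.rot90(masks["inner"], k).shape
    masks = {n: np.ascontiguousarray(np.rot90(m, k)) for n, m in masks.items()}

    inner_skel = geometry.thin(masks["inner"])
    outer_skel = geometry.thin(masks["outer"])
    slayer_skel = geometry.thin(masks["slayer"])

    origins, normals, n_skipped = geometry.estimate_normals(
        inner_skel, interior_reference=masks["inner"], neighborhood=params.neighborhood
    )
    if len(origins) == 0:
        return None
    max_len_px = params.max_ray_length_nm / pixel_size
    slayer_hit, slayer_dist, om_dist, om_n, om_reason = _measure_rays(
        origins.astype(np.float64),
        np.ascontiguousarray(normals),
        np.ascontiguousarray(slayer_skel),
        np.ascontiguousarray(outer_skel),
        float(max_len_px),
        params.max_hit_pixels,
    )
    origins_out = geometry.rotate_points(origins, -k, shape_c).astype(int)
    return {
        "origins": origins_out,
        "slayer_hit": slayer_hit,
        "slayer_dist_px": slayer_dist,
        "om_dist_px": om_dist,
        "om_n_hits": om_n,
        "om_reason": om_reason,
        "n_skipped": n_skipped,
    }


def measure_cell(stack: SegmentationStack, params: MeasureParams | None = None) -> CellMeasurements:
    """Run the full per-cell measurement over an already slab-extracted stack.

    For every slice: thin the three structures, estimate inner-membrane
    normals, cast a thin ray per pixel against the S-layer and a 3-px-thick
    ray against the outer membrane, and pool hits, distances and discard
    counters across the slab.
    """
    params = params or MeasureParams()
    px = stack.pixel_size
    out = CellMeasurements(
        cell_id=stack.cell_id,
        pixel_size=px,
        timepoint_label=stack.timepoint_label,
        is_control=stack.is_control,
    )
    slices, rows, cols = [], [], []
    sl_hit, sl_dist, om_dist, om_n, om_reason = [], [], [], [], []
    for z in range(stack.n_slices):
        res = measure_slice(stack.masks[z], px, params)
        if res is None:
            out.n_skipped_slices += 1
            continue
        n = len(res["slayer_hit"])
        slices.append(np.full(n, z))
        rows.append(res["origins"][:, 0])
        cols.append(res["origins"][:, 1])
        sl_hit.append(res["slayer_hit"])
        sl_dist.append(res["slayer_dist_px"] * px)
        om_dist.append(res["om_dist_px"] * px)
        om_n.append(res["om_n_hits"])
        om_reason.append(res["om_reason"])
        out.n_skipped_pixels += res["n_skipped"]
    if slices:
        out.slice_index = np.concatenate(slices)
        out.origin_row = np.concatenate(rows)
        out.origin_col = np.concatenate(cols)
        out.slayer_hit = np.concatenate(sl_hit)
        out.slayer_distance_nm = np.concatenate(sl_dist)
        out.om_distance_nm = np.concatenate(om_dist)
        out.om_n_hits = np.concatenate(om_n)
        out.discard_reason = np.concatenate(om_reason)
        out.om_valid = out.discard_reason == OK
    return out
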