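"""Synthetic cell cross-section phantoms with known ground truth.

The generator rasterizes closed, star-convex cross-sections of a
Gram-negative envelope: a smooth inner membrane, an outer membrane at a
baseline separation carrying optional strictly positive "ruffling"
excursions, and an S-layer shell at a fixed offset outside the outer
membrane with a controllable contiguous-gap coverage fraction.  Because the
generating curves are analytic, every downstream stage (skeletonization,
normal estimation, ray casting, the coverage and ruffling statistics) can be
validated against exact ground truth without tomograms.

Geometry model
--------------
The inner membrane is a star-convex curve ``r_in(theta) = R (1 + sum_k a_k
cos(k theta + phi_k))`` with a few low-order harmonics, so phantoms are
cell-like ovoids rather than circles (circles remain the degenerate case at
``shape_amplitude = 0``).  The outer membrane sits at radial separation
``s(theta) = baseline + jitter(theta) + ruffle(theta)``:

* ``jitter`` emulates the control separation distribution.  It is the
  absolute value of a smooth random Fourier field whose pointwise marginal is
  N(0, jitter_sd^2), so the pointwise jitter law is half-normal with scale
  ``jitter_sd`` while remaining smooth along the perimeter.  Half-normal
  (positive-only) noise matches the observation that membrane deformations
  only ever increase the separation.
* ``ruffle`` places a few flat-topped smooth bumps of height
  ``ruffle_amplitude`` whose plateaus cover ``ruffle_fraction`` of the
  perimeter, emulating localized outer-membrane ruffling.

The S-layer lies at ``r_out(theta) + slayer_offset`` wherever it has not been
lost; loss is modeled as ``n_gaps`` contiguous arcs (sheet-like loss, not
speckle) totalling ``1 - coverage_fraction`` of the perimeter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LABEL_INNER, LABEL_OUTER, LABEL_SLAYER, SegmentationStack, save_stack

_N_THETA = 4096  # angular samples of the analytic profiles


class GeometryOverflowError(ValueError):
    """Raised when the outermost contour would leave the image."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cell cross-section.

    Lengths are in nm.  Defaults describe a plausible *C. crescentus*-like
    envelope rasterized at 1.29 nm/pixel (6.45 A acquisition binned by two).
    """

    inner_radius: float = 65.0
    baseline_separation: float = 16.0
    slayer_offset: float = 18.0
    coverage_fraction: float = 1.0
    n_gaps: int = 2
    ruffle_fraction: float = 0.0
    ruffle_amplitude: float = 0.0
    jitter_sd: float = 1.5
    pixel_size: float = 1.29
    n_slices: int = 50
    image_size: int = 256
    seed: int = 0
    #: relative amplitude of the low-order shape harmonics of the inner radius
    shape_amplitude: float = 0.02
    shape_harmonics: tuple = (2, 3)
    #: number of Fourier modes in the smooth jitter field
    jitter_harmonics: int = 12
    #: number of flat-topped ruffle bumps sharing ruffle_fraction of perimeter
    n_ruffles: int = 3
    #: draw an independent jitter field for every slice
    per_slice_jitter: bool = False
    #: rasterize contours single-pixel wide instead of the default 2-pixel
    prethinned: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in [0, 1]")
        if not 0.0 <= self.ruffle_fraction <= 1.0:
            raise ValueError("ruffle_fraction must be in [0, 1]")
        for name in ("inner_radius", "baseline_separation", "slayer_offset", "pixel_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.ruffle_amplitude < 0 or self.jitter_sd < 0:
            raise ValueError("ruffle_amplitude and jitter_sd must be non-negative")
        if self.n_slices < 1 or self.image_size < 32:
            raise ValueError("n_slices must be >= 1 and image_size >= 32")
        r_max_nm = (
            self.inner_radius * (1.0 + self.shape_amplitude)
            + self.baseline_separation
            + self.ruffle_amplitude
            + self.slayer_offset
        )
        if r_max_nm / self.pixel_size + 10 > self.image_size / 2:
            raise GeometryOverflowError(
                f"contours of radius {r_max_nm:.1f} nm do not fit a "
                f"{self.image_size}-px image at {self.pixel_size} nm/px with 10 px margin"
            )


@dataclass
class PhantomTruth:
    """Analytic ground truth of a phantom, sampled on a dense angular grid."""

    theta: np.ndarray
    #: separation in nm; (n_theta,) for slice-invariant phantoms,
    #: (n_slices, n_theta) when per-slice jitter was requested
    separation_profile: np.ndarray
    slayer_present: np.ndarray
    true_coverage_fraction: float
    #: analytic inner-membrane radius r(theta) in nm
    inner_radius_profile: np.ndarray = None

    @property
    def true_separation_profile(self) -> np.ndarray:
        return self.separation_profile

    def true_extreme_fraction(self, threshold_nm: float) -> float:
        """Perimeter fraction whose separation exceeds ``threshold_nm``."""
        return float(np.mean(self.separation_profile > threshold_nm))


def _arc_layout(rng: np.random.Generator, n_arcs: int, total_measure: float):
    """Centers and half-widths of non-overlapping arcs with given total angular measure.

    The circle is split into ``n_arcs`` equal sectors and one arc is placed at
    a random position inside each sector, which guarantees non-overlap.
    """
    if n_arcs < 1 or total_measure <= 0:
        return np.empty(0), np.empty(0)
    half = total_measure / (2.0 * n_arcs)
    sector = 2.0 * np.pi / n_arcs
    lo = half
    hi = sector - half
    offs = rng.uniform(lo, max(hi, lo + 1e-9), size=n_arcs)
    centers = np.arange(n_arcs) * sector + offs
    return centers % (2 * np.pi), np.full(n_arcs, half)


def _angular_distance(theta: np.ndarray, center: float) -> np.ndarray:
    d = np.abs((theta - center + np.pi) % (2 * np.pi) - np.pi)
    return d


def _smooth_halfnormal_field(rng, theta, sd: float, n_harmonics: int) -> np.ndarray:
    """|Gaussian Fourier field| with pointwise half-normal(sd) marginal."""
    if sd == 0:
        return np.zeros_like(theta)
    k = np.arange(1, n_harmonics + 1)
    scale = sd / np.sqrt(n_harmonics)
    a = rng.normal(0.0, scale, size=n_harmonics)
    b = rng.normal(0.0, scale, size=n_harmonics)
    g = (a[:, None] * np.cos(k[:, None] * theta) + b[:, None] * np.sin(k[:, None] * theta)).sum(axis=0)
    return np.abs(g)


def _ruffle_profile(theta, centers, halfs, amplitude: float, taper: float = 0.08) -> np.ndarray:
    """Flat-topped bumps: plateau at ``amplitude`` inside each arc, raised-cosine taper outside."""
    prof = np.zeros_like(theta)
    for c, h in zip(centers, halfs):
        d = _angular_distance(theta, c)
        plateau = d <= h
        ramp = (d > h) & (d < h + taper)
        prof[plateau] = np.maximum(prof[plateau], amplitude)
        prof[ramp] = np.maximum(prof[ramp], amplitude * 0.5 * (1 + np.cos(np.pi * (d[ramp] - h) / taper)))
    return prof


def _covered_mask(theta, gap_centers, gap_halfs) -> np.ndarray:
    covered = np.ones_like(theta, dtype=bool)
    for c, h in zip(gap_centers, gap_halfs):
        covered &= _angular_distance(theta, c) > h
    return covered


def _rasterize_band(canvas, points_px, normals, covered=None, width_px=2.0):
    """Mark a band of ``width_px`` extent along a parametric curve into ``canvas``.

    ``points_px`` is (n, 2) of (row, col) curve samples; the band grows along
    the per-sample outward ``normals``.
    """
    if covered is not None:
        points_px = points_px[covered]
        normals = normals[covered]
        if len(points_px) == 0:
            return
    # band centred on the analytic curve so skeletonization cannot drift a
    # full pixel to either side
    half = (width_px - 1.0) / 2.0
    offsets = np.arange(-half, half + 1e-9, 0.5) if width_px > 1 else np.array([0.0])
    pts = points_px[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    rows = np.round(pts[..., 0]).astype(np.intp).ravel()
    cols = np.round(pts[..., 1]).astype(np.intp).ravel()
    H, W = canvas.shape
    if rows.min() < 0 or rows.max() >= H or cols.min() < 0 or cols.max() >= W:
        raise GeometryOverflowError("contour leaves the image")
    canvas[rows, cols] = True


def generate_phantom(spec: PhantomSpec) -> tuple[SegmentationStack, PhantomTruth]:
    """Rasterize one phantom cell and return it with its analytic truth.

    Fully reproducible: identical ``spec`` (including ``seed``) yields a
    byte-identical stack.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    theta = np.linspace(0.0, 2 * np.pi, _N_THETA, endpoint=False)
    px = spec.pixel_size

    # inner-membrane radius profile (nm)
    r_in = np.full(_N_THETA, spec.inner_radius)
    if spec.shape_amplitude > 0 and spec.shape_harmonics:
        amp = spec.shape_amplitude * spec.inner_radius / len(spec.shape_harmonics)
        for k in spec.shape_harmonics:
            phase = rng.uniform(0, 2 * np.pi)
            r_in = r_in + amp * np.cos(k * theta + phase)

    # ruffle bumps (shared across slices: ruffles are structural)
    ruff_centers, ruff_halfs = _arc_layout(rng, spec.n_ruffles, spec.ruffle_fraction * 2 * np.pi)
    ruffle = (
        _ruffle_profile(theta, ruff_centers, ruff_halfs, spec.ruffle_amplitude)
        if spec.ruffle_fraction > 0 and spec.ruffle_amplitude > 0
        else np.zeros(_N_THETA)
    )

    # S-layer gap arcs
    if spec.coverage_fraction >= 1.0:
        covered = np.ones(_N_THETA, dtype=bool)
        true_cov = 1.0
    elif spec.coverage_fraction <= 0.0:
        covered = np.zeros(_N_THETA, dtype=bool)
        true_cov = 0.0
    else:
        gap_measure = (1.0 - spec.coverage_fraction) * 2 * np.pi
        gap_centers, gap_halfs = _arc_layout(rng, spec.n_gaps, gap_measure)
        covered = _covered_mask(theta, gap_centers, gap_halfs)
        true_cov = 1.0 - float(np.sum(2 * gap_halfs)) / (2 * np.pi)

    n_jitter_fields = spec.n_slices if (spec.per_slice_jitter and spec.jitter_sd > 0) else 1
    separations = np.empty((n_jitter_fields, _N_THETA))
    for i in range(n_jitter_fields):
        jitter = _smooth_halfnormal_field(rng, theta, spec.jitter_sd, spec.jitter_harmonics)
        separations[i] = spec.baseline_separation + jitter + ruffle

    center = ((spec.image_size - 1) / 2.0, (spec.image_size - 1) / 2.0)
    width = 1.0 if spec.prethinned else 2.0
    shape2d = (spec.image_size, spec.image_size)

    # dense parametric sampling of the inner curve and its outward normals;
    # outer membrane and S-layer are offset ALONG THE NORMAL, so the truth
    # separation profile is exactly the quantity normal-ray casting measures
    r_max_px = (r_in.max() + separations.max() + spec.slayer_offset) / px
    n_samp = max(_N_THETA, int(np.ceil(2 * np.pi * r_max_px / 0.2)))
    th_d = np.linspace(0.0, 2 * np.pi, n_samp, endpoint=False)
    r_d = np.interp(th_d, theta, r_in, period=2 * np.pi) / px
    p_in = np.column_stack([center[0] + r_d * np.sin(th_d), center[1] + r_d * np.cos(th_d)])
    tang = np.gradient(p_in, axis=0)
    nrm = np.column_stack([tang[:, 1], -tang[:, 0]])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    out_sign = np.einsum("ij,ij->i", nrm, p_in - np.array(center))
    nrm[out_sign < 0] *= -1
    covered_d = (
        np.interp(th_d, theta, covered.astype(float), period=2 * np.pi) > 0.5
        if covered.any()
        else np.zeros(n_samp, dtype=bool)
    )

    def _raster_slice(sep_nm: np.ndarray) -> np.ndarray:
        sep_d = np.interp(th_d, theta, sep_nm, period=2 * np.pi) / px
        inner = np.zeros(shape2d, dtype=bool)
        outer = np.zeros(shape2d, dtype=bool)
        slayer = np.zeros(shape2d, dtype=bool)
        _rasterize_band(inner, p_in, nrm, width_px=width)
        _rasterize_band(outer, p_in + sep_d[:, None] * nrm, nrm, width_px=width)
        if covered_d.any():
            _rasterize_band(
                slayer,
                p_in + (sep_d + spec.slayer_offset / px)[:, None] * nrm,
                nrm,
                covered=covered_d,
                width_px=width,
            )
        if (inner & outer).any() or (outer & slayer).any() or (inner & slayer).any():
            raise GeometryOverflowError("structure contours overlap; spec too tight")
        labels = np.zeros(shape2d, dtype=np.uint8)
        labels[inner] = LABEL_INNER
        labels[outer] = LABEL_OUTER
        labels[slayer] = LABEL_SLAYER
        return labels

    if n_jitter_fields == 1:
        one = _raster_slice(separations[0])
        masks = np.repeat(one[None], spec.n_slices, axis=0)
        sep_profile = separations[0]
    else:
        masks = np.stack([_raster_slice(s) for s in separations])
        sep_profile = separations

    stack = SegmentationStack(masks=masks, pixel_size=px, cell_id=f"phantom_{spec.seed}")
    truth = PhantomTruth(
        theta=theta,
        separation_profile=sep_profile,
        slayer_present=covered,
        true_coverage_fraction=true_cov,
        inner_radius_profile=r_in,
    )
    return stack, truth


def _child_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def generate_cohort(
    specs: dict,
    cells_per_timepoint,
    out_dir,
    control_labels: tuple = ("control",),
    fmt: str = "tiff",
    base_seed: int = 0,
) -> pd.DataFrame:
    """Write a cohort of phantom stacks plus an experiment manifest.

    Parameters
    ----------
    specs
        ``{timepoint_label: PhantomSpec}``; per-cell seeds are derived
        deterministically from ``base_seed`` so the cohort is reproducible.
    cells_per_timepoint
        int, or ``{timepoint_label: int}``.
    control_labels
        Labels treated as the unstimulated control; at least one must be
        present in ``specs``.

    Returns
    -------
    manifest : DataFrame with columns cell_id, timepoint_label, is_control,
        path (also written to ``out_dir/manifest.csv``).
    """
    if not any(lbl in specs for lbl in control_labels):
        raise ValueError(f"no control timepoint among {list(specs)}; expected one of {control_labels}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".tif" if fmt.lower() in ("tif", "tiff") else ".mrc"

    n_total = sum(
        cells_per_timepoint[lbl] if isinstance(cells_per_timepoint, dict) else cells_per_timepoint
        for lbl in specs
    )
    seeds = iter(_child_seeds(base_seed, n_total))

    rows = []
    truths = {}
    seen = set()
    for label, spec in specs.items():
        n_cells = cells_per_timepoint[label] if isinstance(cells_per_timepoint, dict) else cells_per_timepoint
        is_control = label in control_labels
        for i in range(n_cells):
            cell_id = f"{label}_cell{i:02d}"
            if cell_id in seen:
                raise ValueError(f"duplicate cell id {cell_id!r}")
            seen.add(cell_id)
            cell_spec = replace(spec, seed=next(seeds))
            stack, truth = generate_phantom(cell_spec)
            stack.cell_id = cell_id
            stack.timepoint_label = label
            stack.is_control = is_control
            path = out_dir / f"{cell_id}{suffix}"
            save_stack(stack, path)
            truths[cell_id] = truth
            rows.append(
                {"cell_id": cell_id, "timepoint_label": label, "is_control": is_control, "path": str(path)}
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth_summary = pd.DataFrame(
        {
            "cell_id": list(truths),
            "true_coverage_fraction": [t.true_coverage_fraction for t in truths.values()],
        }
    )
    truth_summary.to_csv(out_dir / "truth.csv", index=False)
    return manifest
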