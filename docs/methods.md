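# Methods

## Measurement model

The pipeline operates strictly per 2D slice on integer label masks
(1 = inner membrane, 2 = outer membrane, 3 = S-layer). All physical
quantities are in nanometres; the default pixel size is 1.29 nm/px
(a 6.45 Å acquisition binned by two).

**Slab extraction.** "Middle slices of the cell" are interpreted relative to
the cell's own extent: the slab of `slab_slices` (default 50) slices is
centred on the midpoint of the slice range in which the inner membrane is
present, not on the volume midpoint. If fewer slices qualify, all are used
and the stack is flagged (`slab_shortfall`). Contiguous z-slices are
assumed; no re-orientation along the cell axis is attempted.

**Cleaning.** Interactive inside/outside cleaning is replaced by a
largest-8-connected-component filter per structure per slice
(`MeasureParams.clean_components`, on by default, not applied to the
S-layer, which is legitimately fragmented). Continuous probability maps are
binarized with a single user-supplied scalar threshold per tomogram.

**Thinning.** Iterative homotopic thinning to convergence
(`skimage.morphology.thin`, the standard equivalent of MATLAB
`bwmorph('thin', Inf)`). The conformance surface is behavioural: idempotent,
support-preserving, closed contours stay closed as single-pixel 8-connected
curves. Pixel-level thinning templates are not symmetric under 90°
rotations, yet the tomogram's in-plane axes are arbitrary; `thin`,
`estimate_normals` and the per-slice measurement therefore canonicalize the
mask orientation (the lexicographically smallest of the four rotations of
the packed mask bytes), operate there, and rotate results back. Rotating
integer pixel coordinates and unit vectors by quarter turns is exact, so
every reported statistic is bit-exactly invariant under 90° rotations of
the input.

**Normals.** At each inner-membrane curve pixel the tangent is the
principal axis (total-least-squares line fit, closed-form 2×2
eigenvector) of the curve pixels within an *along-curve* distance of
`neighborhood` (default 10) pixels; the along-curve metric prevents the
opposite cell wall from contaminating the fit at narrow necks of
predivisional cells. The normal is the tangent rotated 90°, oriented
outward against the per-slice inner-membrane centroid. Junction pixels
(≥3 curve neighbours) and isolated pixels are skipped and counted.
On rasterized circles the maximum angular error is < 3°; on star-convex
phantoms the mean error is < 1°.

**Ray casting.** Rays are walked with a supercover traversal (every pixel
the continuous line passes through; at an exact corner crossing both side
pixels are visited), so a single-pixel ray cannot tunnel diagonally through
an 8-connected curve. The S-layer is probed with a single-pixel ray
(presence/absence; the first-hit distance is recorded but unused by the
coverage statistic). The outer membrane is probed with a three-pixel-thick
ray — the central line plus two parallel lines offset ±1 px perpendicular,
hit pixels deduplicated — and the separation is the mean Euclidean distance
from the origin pixel centre to each intersected outer-membrane pixel
centre (sorted before summation so the result is independent of traversal
order). Measurements with more than `max_hit_pixels` (default 4) raw pixel
hits are discarded as noisy; zero hits within `max_ray_length_nm` (default
100 nm, generously above the control 99th percentile plus the S-layer
offset, yet short enough not to wrap to neighbouring cells) are discarded
as no-hits. No subpixel interpolation is applied; at ~1.3 nm pixels the
quantization is the resolution floor of the method (per-ray separation
noise sd ≈ 0.7 nm on phantoms).

**Statistics.** Coverage = S-layer hits / rays, pooled over the cell's
slab; extreme-separation fraction = valid separations above threshold /
valid separations, per cell. The two statistics use independent validity
filters: the >4-pixel rule belongs to the outer-membrane measurement only.
The threshold is a percentile (default 99, linear interpolation between
order statistics) of the valid separations pooled across all control cells;
control pools below 100 distances trigger an instability warning.
Per-timepoint means and SEMs are computed over single-cell values, never
over pooled rays — so one cell gives SEM 0. Report histograms use 1-nm
bins, but the statistic itself counts raw distances (the bin-free limit of
integrating a histogram above a threshold).

## Synthetic phantoms

Phantoms emulate closed, roughly convex cell cross-sections:

* **Inner membrane**: star-convex r(θ) = R(1 + Σₖ aₖ cos(kθ+φₖ)) with
  harmonics (2, 3) and total relative amplitude 2% — a smooth cell-like
  ovoid; amplitude 0 recovers the circle as the degenerate test case.
  Default R = 65 nm (plausible for *C. crescentus*; no cell-size statistics
  are published to calibrate against).
* **Outer membrane**: offset from the inner curve *along its analytic
  normals* by s(θ) = 16 nm + jitter + ruffle, so the truth separation
  profile is by construction the quantity normal-ray casting measures.
  Jitter is the absolute value of a smooth random Fourier field (12
  harmonics) whose pointwise marginal is N(0, jitter_sd²); the pointwise
  jitter law is therefore exactly half-normal (scale `jitter_sd`, default
  1.5 nm) while the profile stays smooth. Positive-only noise reflects the
  observation that membrane deformations only increase the separation.
  Ruffles are flat-topped raised-cosine bumps of height `ruffle_amplitude`
  whose plateaus occupy `ruffle_fraction` of the perimeter (≤3 bumps:
  ruffling is localized, not speckled).
* **S-layer**: at a fixed 18 nm offset outside the outer membrane, with
  `n_gaps` (default ≤3) contiguous missing arcs totalling
  1 − coverage_fraction of the perimeter — sheet-like loss.

Contours are rasterized as 2-px-wide bands centred on the analytic curve
(so skeletonization cannot drift a full pixel to one side), or single-pixel
with `prethinned=True`. Slices are identical unless `per_slice_jitter`
draws an independent jitter field per slice. Generation is byte-reproducible
from the seed; cohort seeds derive from one base seed via `SeedSequence`.

What phantoms do **not** emulate: grayscale contrast, the missing wedge,
segmentation errors (false positives/negatives), open or touching cells,
3D curvature along z. Passing recovery tests therefore demonstrates the
correctness of the measurement chain on clean masks, not robustness to
segmentation noise — on real data the coverage of even a fully covered
control is bounded by segmentation quality, not by this pipeline.

The default cohort (`envquant simulate`) is a control plus five timepoints
(264–1315 ms labels) with coverage decaying 1.0 → 0.05 non-uniformly and
ruffling jumping to ~0.25–0.35 of the perimeter already at the first
timepoint — the qualitative time course of acid-induced S-layer shedding.

## Reaction-time budget

Five additive components; uncertainty as interval arithmetic (ranges, not
distributions):

| component | model | default |
|---|---|---|
| t_mix | (w/2)²/4D, w = d·√(Q_s/Q_tot) (cylindrical co-flow: area fraction = flow fraction) | D = 1 µm²/ms |
| t_delay | πr²L / Q_tot (plug flow) | d = 75 µm, L = 20 mm |
| t_flight | empirical range | 1–4 ms |
| t_grid | empirical range (plunge mechanics) | 16–89 ms |
| t_freeze | droplet vitrification | 1 ms |

The mixing model is the standard hydrodynamic-focusing order-of-magnitude
estimate; outputs should be compared with achievable ranges, never exact
timepoints. Strict validation enforces the operating envelope (total flow
35–130 µl/min, stimulant/sample ratio 1.5–5.8, nozzle 80–110 µm);
permissive mode downgrades violations to warnings. Flow unit conversion
(µl/min ↔ nl/s) is factored as (x·50)/3 and (x·3)/50, which round-trips
bit-exactly for every value at pump-setting granularity.

## Numerical choices and problem sizes

* Percentile definition: linear interpolation (`numpy.percentile` default);
  with realistic control pool sizes competing definitions differ by
  < 0.2 nm.
* Distances: origin-pixel-centre to hit-pixel-centre Euclidean, in pixels,
  scaled by pixel size.
* Degenerate inputs: empty masks thin to empty curves; a slice without
  inner membrane is skipped and counted; zero processed rays raise.
* Test and script cohorts use 2–6 slices per cell and 3–24 cells per
  condition — phantom slices are statistically exchangeable, so these sizes
  already give recovery errors well inside the tolerances (coverage MAE
  ≈ 0.005, extreme-fraction MAE ≈ 0.03, threshold within ~0.35 nm of the
  closed-form half-normal quantile).
* Control-threshold validation uses `prethinned` phantoms and ≥ 8 control
  cells: skeletonizing the 2-px raw bands adds ±0.5 px correlated
  quantization that inflates the measured 99th percentile by ≈ +0.4 nm,
  and the smooth jitter fields make rays within a slice correlated, so
  many independent cells are needed for a stable tail quantile.

## Known limitations

* Strictly 2D per slice; no 3D surface normals or curvature-corrected
  distances.
* The orientation canonicalization guarantees exact invariance only for
  90° rotations; arbitrary-angle rotations change the raster and therefore
  the statistics within pixel noise.
* The largest-component filter can delete a legitimately split membrane in
  a pathological slice; disable it for such data.
* Mixer geometries beyond the default are not numerically reproduced here;
  per-mixer calibration data (jet velocities, per-mixer capillary
  dimensions) would be required.
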