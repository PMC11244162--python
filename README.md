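# envquant

Quantification of bacterial envelope remodeling from cryo-electron
tomography segmentations, plus a reaction-time budget model for
mix-and-inject spray-freezing experiments.

## The problem

Time-resolved cryo-ET experiments on Gram-negative bacteria (e.g. an acid
stimulus applied to *Caulobacter crescentus*) produce, for each cell and
reaction timepoint, a stack of 2D segmentation masks labelling the inner
membrane, the outer membrane and the S-layer (the pseudocrystalline protein
shell outside the outer membrane). Two questions are asked of these masks:

1. **How much of the cell surface still carries S-layer?**
2. **How ruffled is the outer membrane** — i.e. what fraction of the
   inner–outer membrane separations is extreme relative to unstimulated
   control cells?

`envquant` implements the full measurement chain:

* extract the 50 middle slices of the cell (centred on the cell's own
  inner-membrane extent, to minimise curvature artifacts);
* thin each structure to single-pixel 8-connected curves (homotopic
  thinning);
* estimate an extracellular-facing unit normal **n̂** at every
  inner-membrane curve pixel from a total-least-squares line fit to the
  curve pixels within 10 px along the curve;
* cast a single-pixel ray along **n̂** against the S-layer (presence/absence
  per ray) and a three-pixel-thick ray against the outer membrane
  (separation = mean Euclidean distance to the intersected outer-membrane
  pixels; measurements touching more than 4 pixels are discarded as noisy);
* reduce per cell and per timepoint:
  coverage = hits / rays, and extreme-separation fraction
  = #{d > d₉₉} / #valid, where d₉₉ is the 99th percentile of the pooled
  control separation distribution. Error bars are SEMs over single-cell
  values.

Because no tomograms are distributed with such studies, the package ships a
**synthetic phantom generator**: star-convex cell cross-sections with an
analytic inner membrane r(θ), an outer membrane offset along the inner
curve's normals by baseline + smooth half-normal jitter + flat-topped
ruffle bumps, and an S-layer shell with contiguous (sheet-like) gaps. Every
phantom carries exact ground truth, so the whole pipeline is validated by
parameter recovery.

A separate module budgets the reaction time of the spray-freezing
apparatus as five additive components
t_rxn = t_mix + t_delay + t_flight + t_grid + t_freeze, with hydrodynamic
focusing width w = d·√(Q_s/Q_tot), diffusive mixing t_mix = (w/2)²/(4D),
plug-flow delay t = V/Q, and interval arithmetic over the empirical flight
(1–4 ms) and on-grid (16–89 ms) windows.

## Worked example

```python
import envquant as eq

# a half-covered, ruffled phantom cell, 12 slices at 1.29 nm/px
spec = eq.PhantomSpec(coverage_fraction=0.5, ruffle_fraction=0.3,
                      ruffle_amplitude=15.0, n_slices=12,
                      per_slice_jitter=True, seed=2)
stack, truth = eq.generate_phantom(spec)
m = eq.measure_cell(stack)
print(f"coverage      {eq.cell_coverage(m):.3f}  (truth {truth.true_coverage_fraction:.3f})")
print(f"extreme frac  {eq.extreme_fraction(m, 20.4):.3f}  (truth {truth.true_extreme_fraction(20.4):.3f})")
print(m.counters())
```

prints

```
coverage      0.504  (truth 0.500)
extreme frac  0.327  (truth 0.356)
{'n_rays': 3408, 'n_skipped_pixels': 0, 'n_skipped_slices': 0,
 'slayer_hits': 1717, 'slayer_misses': 1691, 'om_valid': 3177,
 'om_too_many_hits': 231, 'om_no_hit': 0}
```

i.e. 3408 inner-membrane rays were cast over the slab; 231 thick-ray
separation measurements intersected more than four outer-membrane pixels
and were discarded from the ruffling statistic (but still count for
coverage — the two statistics filter independently).

From the shell, a full cohort run:

```bash
envquant simulate --out cohort --seed 1
envquant quantify --manifest cohort/manifest.csv --out results
envquant timebudget --sample-flow 15 --stimulant-flow 45
```

`results/results.csv` has one row per timepoint with
`mean_coverage`, `sem_coverage`, `mean_extreme_fraction`,
`sem_extreme_fraction` and the shared control threshold in nm.

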