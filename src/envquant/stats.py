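"""Per-timepoint reduction of ray measurements.

Two headline statistics, both computed per cell first and then averaged over
cells within a timepoint (error bars are the standard error of the mean of
single-cell values, never of pooled rays):

* **S-layer coverage** — the fraction of inner-membrane normal rays that
  intersect the S-layer curve.
* **Extreme-separation (ruffling) fraction** — the fraction of valid
  intermembrane distance measurements exceeding a threshold defined once as
  a high percentile (default the 99th) of the pooled control distance
  distribution.

The two statistics use independent validity filters: the >4-pixel discard
rule applies to the outer-membrane measurement only, so rays discarded there
still count for coverage, and vice versa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raycast import CellMeasurements

logger = logging.getLogger(__name__)


@dataclass
class CoverageSummary:
    timepoint_label: str
    per_cell_coverage: np.ndarray
    mean_coverage: float
    sem: float


@dataclass
class RufflingSummary:
    timepoint_label: str
    threshold_nm: float
    per_cell_extreme_fraction: np.ndarray
    mean_extreme_fraction: float
    sem: float


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def cell_coverage(m: CellMeasurements) -> float:
    """Fraction of processed rays that intersect the S-layer, pooled over the slab."""
    n = m.n_rays
    if n == 0:
        raise ValueError(f"cell {m.cell_id!r}: no processed rays")
    return float(m.slayer_hit.sum()) / n


def control_threshold(control_cells, percentile: float = 99.0) -> float:
    """Percentile of the pooled valid control distances, in nm.

    Distances from all control cells are pooled before the percentile is
    taken (the control sample has one distance distribution); linear
    interpolation between order statistics.
    """
    if not control_cells:
        raise ValueError("no control cells")
    pooled = np.concatenate([m.valid_distances_nm for m in control_cells])
    if pooled.size == 0:
        raise ValueError("no valid control distances")
    if pooled.size < 100:
        warnings.warn(
            f"only {pooled.size} control distances pooled; the {percentile}th "
            "percentile threshold may be unstable",
            stacklevel=2,
        )
    return float(np.percentile(pooled, percentile))


def extreme_fraction(m: CellMeasurements, threshold_nm: float) -> float:
    """Fraction of this cell's valid distances exceeding ``threshold_nm``."""
    d = m.valid_distances_nm
    if d.size == 0:
        raise ValueError(f"cell {m.cell_id!r}: no valid distances")
    return float(np.sum(d > threshold_nm)) / d.size


def distance_histogram(measurements, bin_width: float = 1.0):
    """Pooled distance histogram with fixed-width bins (nm)."""
    pooled = np.concatenate([m.valid_distances_nm for m in measurements])
    if pooled.size == 0:
        return np.array([0.0, bin_width]), np.array([], dtype=int)
    hi = np.ceil(pooled.max() / bin_width) * bin_width + bin_width
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(pooled, bins=edges)
    return edges, counts


def summarize(
    manifest: pd.DataFrame,
    measurements,
    percentile: float = 99.0,
    bin_width: float = 1.0,
):
    """Reduce per-cell measurements to per-timepoint summaries.

    Parameters
    ----------
    manifest
        DataFrame with columns cell_id, timepoint_label, is_control; every
        measured cell must appear in it.
    measurements
        list of :class:`CellMeasurements` (or dict cell_id -> measurement).

    Returns
    -------
    coverage : list of CoverageSummary (one per timepoint, manifest order)
    ruffling : list of RufflingSummary
    results : tidy DataFrame, one row per timepoint
    histograms : dict timepoint_label -> (bin_edges, counts)
    """
    if isinstance(measurements, dict):
        by_cell = dict(measurements)
    else:
        by_cell = {m.cell_id: m for m in measurements}
    missing = set(by_cell) - set(manifest["cell_id"])
    if missing:
        raise ValueError(f"measured cells not in manifest: {sorted(missing)}")

    control_ids = manifest.loc[manifest["is_control"].astype(bool), "cell_id"]
    control_cells = [by_cell[c] for c in control_ids if c in by_cell]
    threshold = control_threshold(control_cells, percentile)

    coverage, ruffling, rows = [], [], []
    histograms = {}
    for label in manifest["timepoint_label"].drop_duplicates():
        ids = manifest.loc[manifest["timepoint_label"] == label, "cell_id"]
        cells = [by_cell[c] for c in ids if c in by_cell]
        if not cells:
            raise ValueError(f"timepoint {label!r} has zero measured cells")
        cov = np.array([cell_coverage(m) for m in cells])
        ext = np.array([extreme_fraction(m, threshold) for m in cells])
        coverage.append(CoverageSummary(label, cov, float(cov.mean()), _sem(cov)))
        ruffling.append(RufflingSummary(label, threshold, ext, float(ext.mean()), _sem(ext)))
        histograms[label] = distance_histogram(cells, bin_width)
        rows.append(
            {
                "timepoint": label,
                "n_cells": len(cells),
                "mean_coverage": float(cov.mean()),
                "sem_coverage": _sem(cov),
                "mean_extreme_fraction": float(ext.mean()),
                "sem_extreme_fraction": _sem(ext),
                "threshold_nm": threshold,
            }
        )
    return coverage, ruffling, pd.DataFrame(rows), histograms


def per_cell_table(manifest: pd.DataFrame, measurements, threshold_nm: float) -> pd.DataFrame:
    """One row per cell: coverage, extreme fraction, ray counters."""
    if isinstance(measurements, dict):
        by_cell = dict(measurements)
    else:
        by_cell = {m.cell_id: m for m in measurements}
    rows = []
    for _, rec in manifest.iterrows():
        m = by_cell.get(rec["cell_id"])
        if m is None:
            continue
        rows.append(
            {
                "cell_id": m.cell_id,
                "timepoint": rec["timepoint_label"],
                "is_control": bool(rec["is_control"]),
                "coverage": cell_coverage(m),
                "extreme_fraction": extreme_fraction(m, threshold_nm),
                **m.counters(),
            }
        )
    return pd.DataFrame(rows)
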