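"""Coverage/ruffling statistics: closed-form oracles and structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import halfnorm

from envquant import (
    PhantomSpec,
    cell_coverage,
    control_threshold,
    extreme_fraction,
    generate_phantom,
    measure_cell,
    summarize,
)
from envquant.raycast import CellMeasurements
from envquant.stats import _sem, per_cell_table


def _fake_measurement(cell_id, hits, distances, valid=None):
    hits = np.asarray(hits, dtype=bool)
    distances = np.asarray(distances, dtype=float)
    valid = np.ones(len(distances), dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    return CellMeasurements(
        cell_id=cell_id,
        pixel_size=1.0,
        slayer_hit=hits,
        om_distance_nm=distances,
        om_valid=valid,
        discard_reason=np.where(valid, 0, 1),
    )


def test_cell_coverage_pools_rays():
    m = _fake_measurement("c", [1, 1, 0, 0], [10, 10, 10, 10])
    assert cell_coverage(m) == 0.5
    with pytest.raises(ValueError):
        cell_coverage(_fake_measurement("c", [], []))


def test_coverage_excludes_nothing_for_om_discards():
    """The >4-pixel rule filters the ruffling statistic only, not coverage."""
    m = _fake_measurement("c", [1, 0, 1, 1], [10, 10, 30, 10], valid=[1, 1, 0, 1])
    assert cell_coverage(m) == 0.75
    assert extreme_fraction(m, 20.0) == 0.0  # invalid 30 nm excluded


def test_control_threshold_halfnormal_closed_form():
    """99th percentile of measured control distances vs the closed-form quantile."""
    cells = []
    for s in range(8):
        spec = PhantomSpec(n_slices=5, per_slice_jitter=True, jitter_sd=1.5,
                           prethinned=True, seed=200 + s)
        stack, _ = generate_phantom(spec)
        cells.append(measure_cell(stack))
    n = sum(len(c.valid_distances_nm) for c in cells)
    assert n >= 5000
    thr = control_threshold(cells, 99)
    analytic = 16.0 + halfnorm.ppf(0.99, scale=1.5)
    assert abs(thr - analytic) < 0.5


def test_control_threshold_degenerate_distribution(concentric_stack):
    """Constant separation: any percentile equals that separation within a pixel."""
    m = measure_cell(concentric_stack)
    thr = control_threshold([m], 99)
    assert abs(thr - 16.0) < 1.0  # 1 px at 1 nm/px


def test_median_of_symmetric_jitter_near_baseline():
    cells = []
    for s in range(2):
        spec = PhantomSpec(n_slices=4, per_slice_jitter=True, jitter_sd=1.5, seed=300 + s)
        stack, _ = generate_phantom(spec)
        cells.append(measure_cell(stack))
    med = control_threshold(cells, 50)
    analytic = 16.0 + halfnorm.ppf(0.5, scale=1.5)
    assert abs(med - analytic) < 0.7


def test_control_threshold_errors_and_warning():
    with pytest.raises(ValueError):
        control_threshold([])
    small = _fake_measurement("c", [1], np.full(10, 16.0))
    with pytest.warns(UserWarning, match="unstable"):
        control_threshold([small])


def test_extreme_fraction_values_and_monotonicity():
    m = _fake_measurement("c", [1] * 10, np.arange(10.0, 30.0, 2.0))
    fracs = [extreme_fraction(m, t) for t in np.linspace(5, 35, 13)]
    assert all(a >= b for a, b in zip(fracs, fracs[1:]))
    assert extreme_fraction(m, 5.0) == 1.0
    assert extreme_fraction(m, 35.0) == 0.0


def test_extreme_fraction_self_consistency_at_own_percentile():
    """Scoring the control against its own 99th percentile gives ~1%."""
    spec = PhantomSpec(n_slices=6, per_slice_jitter=True, jitter_sd=1.5, seed=400)
    stack, _ = generate_phantom(spec)
    m = measure_cell(stack)
    thr = control_threshold([m], 99)
    frac = extreme_fraction(m, thr)
    assert frac == pytest.approx(0.01, abs=0.005)


def test_zero_ruffle_above_baseline_threshold(concentric_stack):
    m = measure_cell(concentric_stack)
    assert extreme_fraction(m, 20.4) == 0.0


def test_sem_over_cells_not_rays():
    assert _sem(np.array([0.5])) == 0.0
    vals = np.array([0.2, 0.4, 0.6])
    assert _sem(vals) == pytest.approx(np.std(vals, ddof=1) / np.sqrt(3))


def test_summarize_structure():
    manifest = pd.DataFrame(
        {
            "cell_id": ["ctl_a", "ctl_b", "t1_a", "t1_b"],
            "timepoint_label": ["control", "control", "t264ms", "t264ms"],
            "is_control": [True, True, False, False],
        }
    )
    rng = np.random.default_rng(0)
    ms = [
        _fake_measurement("ctl_a", rng.random(200) < 0.9, rng.normal(16, 1, 200)),
        _fake_measurement("ctl_b", rng.random(200) < 0.9, rng.normal(16, 1, 200)),
        _fake_measurement("t1_a", rng.random(200) < 0.5, rng.normal(20, 2, 200)),
        _fake_measurement("t1_b", rng.random(200) < 0.5, rng.normal(20, 2, 200)),
    ]
    coverage, ruffling, results, hists = summarize(manifest, ms)
    assert [c.timepoint_label for c in coverage] == ["control", "t264ms"]
    assert len(results) == 2 and set(results.columns) >= {
        "timepoint", "n_cells", "mean_coverage", "sem_coverage",
        "mean_extreme_fraction", "sem_extreme_fraction", "threshold_nm",
    }
    # SEM is over per-cell values
    cov = coverage[0]
    assert cov.sem == pytest.approx(np.std(cov.per_cell_coverage, ddof=1) / np.sqrt(2))
    assert ruffling[0].threshold_nm == ruffling[1].threshold_nm
    edges, counts = hists["control"]
    assert counts.sum() == 400
    assert np.allclose(np.diff(edges), 1.0)
    table = per_cell_table(manifest, ms, ruffling[0].threshold_nm)
    assert len(table) == 4


def test_summarize_requires_measured_timepoint():
    manifest = pd.DataFrame(
        {
            "cell_id": ["ctl_a", "t1_a"],
            "timepoint_label": ["control", "t264ms"],
            "is_control": [True, False],
        }
    )
    ms = [_fake_measurement("ctl_a", [1, 0], [16.0, 17.0])]
    with pytest.raises(ValueError, match="zero measured cells"):
        summarize(manifest, ms)
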