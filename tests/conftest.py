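import numpy as np
import pytest

from envquant import PhantomSpec, SegmentationStack, generate_phantom


def concentric_labels(size=301, r_inner=50.0, r_outer=66.0, r_slayer=None, width=1.0):
    """Label image with concentric circular membranes (analytic radii in px)."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r = np.hypot(yy - c, xx - c)
    lab = np.zeros((size, size), dtype=np.uint8)
    lab[np.abs(r - r_inner) < width] = 1
    lab[np.abs(r - r_outer) < width] = 2
    if r_slayer is not None:
        lab[np.abs(r - r_slayer) < width] = 3
    return lab


@pytest.fixture(scope="session")
def concentric_stack():
    """Inner R=50 px, outer R=66 px, full S-layer ring at 82 px; 1 nm/px."""
    lab = concentric_labels(r_slayer=82.0)
    return SegmentationStack(masks=lab[None], pixel_size=1.0, cell_id="concentric")


@pytest.fixture(scope="session")
def quiet_phantom():
    """Jitter-free star-convex phantom with full S-layer, one slice."""
    spec = PhantomSpec(n_slices=1, jitter_sd=0.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def gapped_phantom():
    """Half-coverage phantom with two contiguous gaps, no jitter."""
    spec = PhantomSpec(n_slices=1, jitter_sd=0.0, coverage_fraction=0.5, n_gaps=2, seed=12)
    return generate_phantom(spec)


def march_first_hit(origin, direction, mask, max_length_px, step=0.1):
    """Independent continuous ray-marching oracle for the thin-ray cast.

    Samples the continuous ray at fixed parameter steps and returns the
    distance to the centre of the first mask pixel encountered (nan if none).
    """
    t = np.arange(0.0, max_length_px + step, step)
    rr = origin[0] + t * direction[0]
    cc = origin[1] + t * direction[1]
    ir = np.floor(rr + 0.5).astype(int)
    ic = np.floor(cc + 0.5).astype(int)
    inside = (ir >= 0) & (ir < mask.shape[0]) & (ic >= 0) & (ic < mask.shape[1])
    hit = inside & mask[np.clip(ir, 0, mask.shape[0] - 1), np.clip(ic, 0, mask.shape[1] - 1)]
    idx = np.argmax(hit)
    if not hit[idx]:
        return np.nan
    return float(np.hypot(ir[idx] - origin[0], ic[idx] - origin[1]))


def perpendicular_distance(origin, direction, pixel) -> float:
    """Unsigned distance from a pixel centre to the continuous ray line."""
    dr = pixel[0] - origin[0]
    dc = pixel[1] - origin[1]
    return abs(direction[0] * dc - direction[1] * dr)
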