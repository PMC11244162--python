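"""Reading and writing segmentation stacks.

A :class:`SegmentationStack` is the pipeline's raw input: a per-cell stack of
2D label images (one integer label per envelope structure) together with the
physical pixel size in nanometres.  Stacks are stored on disk either as MRC
(CCP-EM) volumes, written through :mod:`gemmi`, or as multipage TIFF written
through :mod:`tifffile`.  Labels follow the canonical scheme
``1 = inner membrane, 2 = outer membrane, 3 = S-layer``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: canonical structure labels
STRUCTURES = {"inner": 1, "outer": 2, "slayer": 3}

LABEL_INNER = STRUCTURES["inner"]
LABEL_OUTER = STRUCTURES["outer"]
LABEL_SLAYER = STRUCTURES["slayer"]

_MRC_SUFFIXES = {".mrc", ".map", ".rec"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


class UnknownFormatError(ValueError):
    """Raised for a file whose suffix is neither MRC nor TIFF."""


@dataclass
class SegmentationStack:
    """Per-cell stack of 2D label masks plus physical pixel size.

    Parameters
    ----------
    masks
        ``(n_slices, H, W)`` integer array; 0 is background, structures use
        the canonical 1/2/3 labels.  A float array is accepted and treated as
        a continuous (probability) map that must be thresholded by
        :func:`binarize`.
    pixel_size
        Physical pixel size in nm/pixel; must be positive.
    """

    masks: np.ndarray
    pixel_size: float
    cell_id: str = ""
    timepoint_label: str = ""
    is_control: bool = False
    slab_shortfall: bool = False

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError(f"masks must be 3D (n_slices, H, W), got shape {self.masks.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def n_slices(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self) -> tuple:
        return self.masks.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, SegmentationStack):
            return NotImplemented
        return (
            np.array_equal(self.masks, other.masks)
            and np.isclose(self.pixel_size, other.pixel_size, rtol=1e-6)
            and self.cell_id == other.cell_id
        )


def save_stack(stack: SegmentationStack, path) -> Path:
    """Write a stack to disk; format chosen from the file suffix.

    MRC volumes store the pixel size in the cell header (in Angstroms, the
    MRC convention).  TIFF stores it in a JSON ImageDescription tag.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    data = np.ascontiguousarray(stack.masks.astype(np.float32))
    if suffix in _MRC_SUFFIXES:
        import gemmi

        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(data)
        ang = stack.pixel_size * 10.0  # nm -> Angstrom
        m.grid.unit_cell = gemmi.UnitCell(
            data.shape[0] * ang, data.shape[1] * ang, data.shape[2] * ang, 90, 90, 90
        )
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))
    elif suffix in _TIFF_SUFFIXES:
        import tifffile

        meta = {"pixel_size_nm": stack.pixel_size, "cell_id": stack.cell_id}
        tifffile.imwrite(
            str(path),
            stack.masks.astype(np.uint8),
            photometric="minisblack",
            description=json.dumps(meta),
        )
    else:
        raise UnknownFormatError(f"unknown output format: {path.name}")
    return path


def _read_mrc(path: Path):
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True)
    uc = m.grid.unit_cell
    # voxel size in Angstrom from cell edge / grid dimension
    vx = uc.a / data.shape[0] if data.shape[0] else 0.0
    pixel_size_nm = vx / 10.0 if vx > 0 else None
    return data, pixel_size_nm


def _read_tiff(path: Path):
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        pixel_size_nm = None
        desc = tf.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
                pixel_size_nm = float(meta.get("pixel_size_nm"))
            except (ValueError, TypeError):
                pixel_size_nm = None
    if data.ndim == 2:
        data = data[None]
    return data, pixel_size_nm


def load_stack(
    path,
    label_map: dict | None = None,
    pixel_size: float | None = None,
    cell_id: str = "",
    timepoint_label: str = "",
    is_control: bool = False,
) -> SegmentationStack:
    """Load an MRC or multipage-TIFF label volume as a SegmentationStack.

    Parameters
    ----------
    label_map
        Optional mapping ``{"inner": lbl, "outer": lbl, "slayer": lbl}`` from
        file labels to structures; labels are remapped to the canonical 1/2/3
        scheme.  When omitted, labels are assumed already canonical.
    pixel_size
        Pixel size in nm/pixel; overrides any value recorded in the header.
        Required if the file carries none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in _MRC_SUFFIXES:
        data, header_px = _read_mrc(path)
    elif suffix in _TIFF_SUFFIXES:
        data, header_px = _read_tiff(path)
    else:
        raise UnknownFormatError(f"unknown input format: {path.name}")

    px = pixel_size if pixel_size is not None else header_px
    if px is None or not px > 0:
        raise ValueError(f"no positive pixel size in header of {path.name}; pass pixel_size=")

    if np.issubdtype(data.dtype, np.floating) and np.allclose(data, np.round(data)):
        data = np.round(data).astype(np.int16)

    if label_map is not None:
        for name in ("inner", "outer"):
            if name not in label_map:
                raise ValueError(f"label_map missing required structure {name!r}")
        remapped = np.zeros_like(data, dtype=np.int16)
        for name, canonical in STRUCTURES.items():
            src = label_map.get(name)
            if src is None:
                continue
            remapped[data == src] = canonical
        data = remapped

    if np.issubdtype(data.dtype, np.integer):
        for name in ("inner", "outer"):
            if not np.any(data == STRUCTURES[name]):
                raise ValueError(f"structure {name!r} (label {STRUCTURES[name]}) absent from {path.name}")
        if not np.any(data == LABEL_SLAYER):
            logger.warning("S-layer label absent from %s; treating as empty S-layer", path.name)
            warnings.warn(f"S-layer label absent from {path.name}", stacklevel=2)

    return SegmentationStack(
        masks=data,
        pixel_size=float(px),
        cell_id=cell_id or path.stem,
        timepoint_label=timepoint_label,
        is_control=is_control,
    )


def central_slab(stack: SegmentationStack, n: int = 50) -> SegmentationStack:
    """Extract the ``n`` slices centred on the cell's own mid-plane.

    The mid-plane is the centre of the slice range in which the inner
    membrane is present — not the volume midpoint — so the slab tracks the
    cell's extent and minimises curvature artifacts near the cell poles.
    If fewer than ``n`` slices carry inner membrane, all of them are
    returned and ``slab_shortfall`` is set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    inner = binarize(stack, "inner")
    occupied = np.flatnonzero(inner.any(axis=(1, 2)))
    if occupied.size == 0:
        raise ValueError(f"no slice of {stack.cell_id!r} contains inner membrane")
    lo, hi = int(occupied[0]), int(occupied[-1])
    n_avail = hi - lo + 1
    if n_avail <= n:
        start, stop = lo, hi + 1
        shortfall = n_avail < n
        if shortfall:
            logger.warning(
                "cell %s: only %d inner-membrane slices available for a %d-slice slab",
                stack.cell_id, n_avail, n,
            )
    else:
        start = (lo + hi + 1) // 2 - n // 2
        stop = start + n
        shortfall = False
    return replace(stack, masks=stack.masks[start:stop], slab_shortfall=shortfall)


def binarize(stack, structure: str, threshold: float | None = None) -> np.ndarray:
    """Per-slice boolean masks for one structure.

    Integer label volumes pass through as ``masks == label``.  Continuous
    (float) maps — e.g. network probability output — require a scalar
    ``threshold``, mirroring per-tomogram threshold selection.
    """
    if structure not in STRUCTURES:
        raise ValueError(f"structure must be one of {sorted(STRUCTURES)}, got {structure!r}")
    masks = stack.masks if isinstance(stack, SegmentationStack) else np.asarray(stack)
    if np.issubdtype(masks.dtype, np.floating):
        if threshold is None:
            raise ValueError("continuous segmentation map requires a threshold")
        return masks >= threshold
    return masks == STRUCTURES[structure]


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component of a 2D boolean mask.

    Replaces the interactive inside/outside cleaning step of manual
    workflows with a reproducible filter; disable via measurement
    parameters when the input is already clean.
    """
    from skimage.measure import label

    if not mask.any():
        return mask
    lab = label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()
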