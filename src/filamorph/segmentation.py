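"""Cell-mask and structure segmentation.

The pipeline works on 16-bit grayscale fluorescence frames of single cells
expressing a filament marker (septin or Cdc42ep1).  Segmentation follows a
fixed recipe:

1. a whole-cell mask from a manual raw-intensity threshold, followed by
   hole filling, morphological opening with a radius-7 disk and removal of
   components below 5,000 px;
2. local background subtraction (image minus its Gaussian blur,
   sigma = 5 px, negatives clamped);
3. structure masks from a channel-specific threshold on the
   background-subtracted image (2,000 for septin, 1,500 for Cdc42ep1),
   restricted to the cell mask, with objects outside the 10-400 px size
   window discarded;
4. an ordered outer-boundary trace of every surviving object (holes are
   ignored), which feeds the Fourier shape descriptors.

Conventions: objects are 8-connected (background 4-connected);
coordinates are 0-based ``(row, col)`` with the origin at the top-left;
thresholds are inclusive (``pixel >= threshold`` is foreground).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk

logger = logging.getLogger("filamorph.segmentation")

MAX_UINT16 = 65535


@dataclass
class ImageFrame:
    """One calibrated grayscale frame.

    ``pixels`` is a 2-D non-negative array in 16-bit range, ``pixel_size``
    the calibration in micrometres per pixel.
    """

    pixels: np.ndarray
    pixel_size: float = 0.1
    channel: str = "septin"
    frame_index: int = 0
    t: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ImageFrame requires a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixels.size and (self.pixels.min() < 0
                                 or self.pixels.max() > MAX_UINT16):
            raise ValueError("intensities must lie in [0, 65535]")


@dataclass
class CellMask:
    """Binary whole-cell mask aligned with its source frame."""

    mask: np.ndarray
    threshold_used: float

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def __bool__(self) -> bool:  # empty masks are valid but falsy
        return bool(self.mask.any())


@dataclass
class StructureObject:
    """One segmented structure: its pixels, outer boundary and bookkeeping."""

    object_id: int
    pixels: np.ndarray              # (n, 2) int (row, col)
    boundary: np.ndarray            # (m, 2) float (row, col), cyclic order
    area: int
    frame_index: int = 0
    cell_id: int = 0
    intensities: Optional[np.ndarray] = None

    @property
    def centroid(self) -> Tuple[float, float]:
        return tuple(self.pixels.mean(axis=0))

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


# ---------------------------------------------------------------------------
# cell mask
# ---------------------------------------------------------------------------

def segment_cell(frame: ImageFrame, cell_threshold: float,
                 open_radius: int = 7, min_cell_area: int = 5000) -> CellMask:
    """Whole-cell mask: threshold, fill holes, open, drop small components.

    An empty result (no component survives the area filter) is returned as
    an empty mask with a warning, not an error.
    """
    img = np.asarray(frame.pixels)
    if not (0 < cell_threshold <= MAX_UINT16):
        raise ValueError("cell_threshold outside the image dynamic range")
    mask = img >= cell_threshold
    mask = ndimage.binary_fill_holes(mask)
    if open_radius > 0:
        mask = ndimage.binary_opening(mask, structure=disk(open_radius))
    mask = _remove_small(mask, min_cell_area)
    if not mask.any():
        logger.warning("cell mask empty after filtering (threshold=%s)",
                       cell_threshold)
    suggestion = suggest_cell_threshold(frame)
    if suggestion is not None:
        logger.info("Otsu cell-threshold suggestion: %.0f (using %.0f)",
                    suggestion, cell_threshold)
    return CellMask(mask=mask, threshold_used=float(cell_threshold))


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop 8-connected components with area below ``min_area``."""
    lab = sk_label(mask, connectivity=2)
    if lab.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(lab.ravel())
    keep = np.nonzero(sizes >= min_area)[0]
    keep = keep[keep != 0]
    return np.isin(lab, keep)


def suggest_cell_threshold(frame: ImageFrame) -> Optional[float]:
    """Otsu-based threshold suggestion; advisory only, never auto-applied."""
    img = np.asarray(frame.pixels)
    if img.size == 0 or np.ptp(img) == 0:
        return None
    return float(threshold_otsu(img.astype(float)))


# ---------------------------------------------------------------------------
# background subtraction
# ---------------------------------------------------------------------------

def subtract_background(frame: ImageFrame, bg_sigma: float = 5.0) -> ImageFrame:
    """Local background subtraction: image minus its Gaussian blur.

    The blurred image (reflective padding at the borders) estimates the
    slowly varying background; subtracting it evens illumination so one
    structure threshold covers bright and dim regions.  Negative residuals
    are clamped to zero.  Calibration metadata is preserved.
    """
    if bg_sigma <= 0:
        raise ValueError("bg_sigma must be positive")
    img = np.asarray(frame.pixels, dtype=float)
    background = ndimage.gaussian_filter(img, sigma=bg_sigma, mode="reflect")
    out = np.clip(img - background, 0.0, None)
    return ImageFrame(pixels=out, pixel_size=frame.pixel_size,
                      channel=frame.channel, frame_index=frame.frame_index,
                      t=frame.t)


# ---------------------------------------------------------------------------
# structure objects
# ---------------------------------------------------------------------------

def segment_structures(bg_subtracted: ImageFrame, mask: CellMask,
                       structure_threshold: float,
                       area_range: Tuple[int, int] = (10, 400),
                       ) -> List[StructureObject]:
    """Label intracellular structures on the background-subtracted frame.

    Components of the thresholded image with more than half of their
    pixels outside the cell mask are dropped entirely; the rest are
    clipped to the mask (robust to the ~1 px erosion the opening applies
    to the mask edge).  Surviving 8-connected components must have an
    area inside the inclusive ``area_range`` window.
    """
    img = np.asarray(bg_subtracted.pixels)
    cm = np.asarray(mask.mask, dtype=bool)
    if img.shape != cm.shape:
        raise ValueError("mask not aligned with image")
    lo, hi = area_range

    fg = img >= structure_threshold
    lab = sk_label(fg, connectivity=2)
    keep = np.zeros_like(fg, dtype=bool)
    if lab.max() > 0:
        ids = np.arange(1, lab.max() + 1)
        total = ndimage.sum_labels(np.ones_like(lab), lab, ids)
        inside = ndimage.sum_labels(cm.astype(float), lab, ids)
        ok = ids[(inside / total) >= 0.5]
        keep = np.isin(lab, ok)
    final_fg = keep & cm
    lab2 = sk_label(final_fg, connectivity=2)

    objects: List[StructureObject] = []
    oid = 0
    for region_id in range(1, lab2.max() + 1):
        rows, cols = np.nonzero(lab2 == region_id)
        area = rows.size
        if area < lo or area > hi:
            continue
        oid += 1
        pix = np.column_stack([rows, cols])
        boundary = trace_boundary(pix)
        objects.append(StructureObject(
            object_id=oid, pixels=pix, boundary=boundary, area=int(area),
            frame_index=bg_subtracted.frame_index,
            intensities=img[rows, cols].astype(float),
        ))
    return objects


# ---------------------------------------------------------------------------
# boundary tracing
# ---------------------------------------------------------------------------

# Moore neighborhood in clockwise order (array coordinates, row downward).
_MOORE = np.array([(0, -1), (-1, -1), (-1, 0), (-1, 1),
                   (0, 1), (1, 1), (1, 0), (1, -1)])


def trace_boundary(pixels: np.ndarray) -> np.ndarray:
    """Ordered outer boundary of an 8-connected pixel set.

    Moore-neighbor tracing started at the lexicographically smallest
    (row, col) pixel.  Interior holes contribute no boundary.  The cyclic
    sequence is returned counter-clockwise in the ``(x, y) = (col, row)``
    frame; the first point is not repeated at the end.  A single pixel
    yields a degenerate 1-point boundary.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.shape[1] != 2 or pixels.shape[0] == 0:
        raise ValueError("pixels must be a non-empty (n, 2) array")
    if pixels.shape[0] == 1:
        return pixels.astype(float)

    rmin, cmin = pixels.min(axis=0)
    local = pixels - [rmin - 1, cmin - 1]          # 1-px pad
    shape = tuple(local.max(axis=0) + 2)
    m = np.zeros(shape, dtype=bool)
    m[local[:, 0], local[:, 1]] = True

    # start: uppermost-leftmost pixel; its west neighbor is background
    start = tuple(local[np.lexsort((local[:, 1], local[:, 0]))][0])
    boundary = [start]
    cur = start
    back_dir = 0                                   # index into _MOORE: west
    first_state = None
    for _ in range(8 * pixels.shape[0] + 8):
        found = False
        for step in range(1, 9):
            d = (back_dir + step) % 8
            nb = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if m[nb]:
                # new backtrack: direction of the previously examined
                # (background) neighbor, as seen from the new pixel
                prev_d = (back_dir + step - 1) % 8
                prev = (cur[0] + _MOORE[prev_d][0], cur[1] + _MOORE[prev_d][1])
                back_dir = _direction_index(nb, prev)
                cur = nb
                found = True
                break
        if not found:                              # isolated pixel
            break
        state = (cur, back_dir)
        if first_state is None:
            first_state = state
        elif state == first_state:
            break
        boundary.append(cur)
    else:  # pragma: no cover - safety net
        logger.warning("boundary trace did not terminate; truncated")

    # drop the duplicated closing point if the trace re-entered the start
    while len(boundary) > 1 and boundary[-1] == start:
        boundary.pop()
    b = np.asarray(boundary, dtype=float) + [rmin - 1, cmin - 1]
    return _orient_ccw(b)


def _direction_index(frm: Tuple[int, int], to: Tuple[int, int]) -> int:
    d = (to[0] - frm[0], to[1] - frm[1])
    for i, (dr, dc) in enumerate(_MOORE):
        if (dr, dc) == d:
            return i
    raise RuntimeError("non-adjacent backtrack")  # pragma: no cover


def _orient_ccw(boundary: np.ndarray) -> np.ndarray:
    """Enforce positive signed area in the (x, y) = (col, row) frame."""
    if boundary.shape[0] < 3:
        return boundary
    x, y = boundary[:, 1], boundary[:, 0]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed < 0:
        boundary = np.vstack([boundary[:1], boundary[1:][::-1]])
    return boundary


def boundary_length(boundary: np.ndarray) -> float:
    """Perimeter of the closed boundary polygon (cyclic polyline length)."""
    if boundary.shape[0] < 2:
        return 0.0
    diffs = np.diff(np.vstack([boundary, boundary[:1]]), axis=0)
    return float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
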