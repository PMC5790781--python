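"""Frame-by-frame lung segmentation seeded by the landmark triangle.

The lung appears dark on bright tissue in gradient-echo cine frames, so
each frame is thresholded with Otsu's method and the below-threshold
component of interest selected: on the reference frame, the component
containing the centroid of the three landmarks; on every other frame,
the component with maximal pixel overlap against the previously
accepted mask, sweeping outward in time from the reference frame.
Masks are regularized by a 3x3 morphological closing followed by hole
filling, so every accepted mask is a single 4-connected, hole-free
region.  Frames whose best candidate overlaps the previous mask with a
Dice coefficient below ``min_overlap`` are flagged invalid and excluded
downstream; losing more than ``max_invalid_fraction`` of the frames
aborts the analysis.

All thresholds and structuring choices are plain config keys
(``segmentation:`` block of the YAML config); nothing is data-adaptive
beyond the per-frame Otsu threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .cine import CineSeries, LandmarkSet

__all__ = ["SegmentationParams", "MaskStack", "dice", "segment_reference",
           "propagate", "extract_contour", "segment_series"]

# 4-connectivity structure for component labelling
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

# Moore neighborhood in clockwise screen order (row down):
# E, SE, S, SW, W, NW, N, NE
_NBRS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass
class SegmentationParams:
    lung_is_dark: bool = True
    min_overlap: float = 0.5            # Dice acceptance vs previous mask
    closing_size: int = 3               # square structuring element side, px
    max_invalid_fraction: float = 0.2


@dataclass
class MaskStack:
    """Per-frame masks, validity flags and boundary contours."""

    masks: np.ndarray                   # (n_frames, rows, cols) bool
    valid: list[bool]
    contours: list[np.ndarray | None]   # (k, 2) int (row, col), None if invalid

    def __len__(self) -> int:
        return self.masks.shape[0]

    @property
    def n_invalid(self) -> int:
        return sum(not v for v in self.valid)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def _threshold(frame: np.ndarray, lung_is_dark: bool) -> np.ndarray:
    """Otsu foreground mask; empty for (near-)uniform frames."""
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        return np.zeros(frame.shape, dtype=bool)
    thr = threshold_otsu(frame)
    return frame < thr if lung_is_dark else frame > thr


def _regularize(mask: np.ndarray, closing_size: int) -> np.ndarray:
    """Morphological closing (square element) then hole filling."""
    se = np.ones((closing_size, closing_size), dtype=bool)
    closed = ndi.binary_closing(mask, structure=se)
    return ndi.binary_fill_holes(closed)


def segment_reference(frame: np.ndarray, landmarks: LandmarkSet,
                      params: SegmentationParams | None = None) -> np.ndarray:
    """Segment the lung on the landmark reference frame.

    The below-threshold connected component containing the landmark
    centroid is kept, then regularized.  Raises if no component covers
    the centroid (e.g. on a uniform-intensity frame).
    """
    params = params or SegmentationParams()
    landmarks.validate_bounds(frame.shape)
    fg = _threshold(frame, params.lung_is_dark)
    labels, n = ndi.label(fg, structure=_FOUR)
    r, c = landmarks.centroid
    seed = (int(round(r)), int(round(c)))
    lab = labels[seed]
    if lab == 0:
        raise ValueError(f"no lung component at seed {seed}")
    mask = _regularize(labels == lab, params.closing_size)
    return mask


def _best_overlap_component(fg: np.ndarray, prev: np.ndarray) -> np.ndarray | None:
    """Foreground component with maximal pixel overlap against ``prev``."""
    labels, n = ndi.label(fg, structure=_FOUR)
    if n == 0:
        return None
    counts = np.bincount(labels[prev], minlength=n + 1)
    counts[0] = 0
    best = int(counts.argmax())
    if counts[best] == 0:
        return None
    return labels == best


def propagate(series: CineSeries, reference_mask: np.ndarray,
              params: SegmentationParams | None = None,
              reference_frame: int = 0) -> MaskStack:
    """Propagate the reference segmentation across every frame.

    Frames are processed in temporal order outward from the reference
    frame in both directions; each frame is re-thresholded and the
    component best overlapping the previously *accepted* mask is taken.
    A frame whose regularized mask has Dice < ``min_overlap`` against
    the previous accepted mask is flagged invalid (the previous mask is
    retained as the tracking anchor).
    """
    params = params or SegmentationParams()
    reference_mask = np.asarray(reference_mask, bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    n = series.n_frames
    if not 0 <= reference_frame < n:
        raise ValueError(f"reference frame {reference_frame} outside series of {n}")

    masks = np.zeros((n,) + series.shape, dtype=bool)
    valid = [False] * n
    masks[reference_frame] = reference_mask
    valid[reference_frame] = True

    for order in (range(reference_frame + 1, n),
                  range(reference_frame - 1, -1, -1)):
        prev = reference_mask
        for k in order:
            fg = _threshold(series.frames[k], params.lung_is_dark)
            comp = _best_overlap_component(fg, prev)
            if comp is None:
                continue  # invalid: nothing overlapping the track
            mask = _regularize(comp, params.closing_size)
            if dice(mask, prev) < params.min_overlap:
                continue  # invalid: track jumped
            masks[k] = mask
            valid[k] = True
            prev = mask

    n_invalid = sum(not v for v in valid)
    if n_invalid > params.max_invalid_fraction * n:
        raise RuntimeError(
            f"tracking lost: {n_invalid} of {n} frames invalid "
            f"(> {params.max_invalid_fraction:.0%} allowed)")

    contours: list[np.ndarray | None] = [
        extract_contour(masks[k]) if valid[k] else None for k in range(n)]
    return MaskStack(masks=masks, valid=valid, contours=contours)


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered boundary polygon of a single-component, hole-free mask.

    Moore-neighbor tracing over the boundary pixels; the first vertex
    is the topmost-then-leftmost boundary pixel and the trace proceeds
    counterclockwise with respect to a y-up frame (east along the top
    edge first, i.e. clockwise on screen where the row axis points
    down).  Vertices are (row, col) pixel coordinates.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot trace an empty mask")
    _, n = ndi.label(mask, structure=_FOUR)
    if n != 1:
        raise ValueError(f"mask has {n} components; expected exactly 1")
    if not np.array_equal(ndi.binary_fill_holes(mask), mask):
        raise ValueError("mask has interior holes")

    pixels = np.argwhere(mask)          # row-major: topmost then leftmost first
    start = tuple(int(v) for v in pixels[0])
    if pixels.shape[0] == 1:
        warnings.warn("single-pixel mask: degenerate 1-vertex contour")
        return pixels.copy()

    rows, cols = mask.shape

    def at(r: int, c: int) -> bool:
        return 0 <= r < rows and 0 <= c < cols and mask[r, c]

    contour: list[tuple[int, int]] = []
    seen: set[tuple[tuple[int, int], int]] = set()
    cur, back = start, 4                # backtrack starts pointing west
    while (cur, back) not in seen:
        seen.add((cur, back))
        contour.append(cur)
        for k in range(1, 9):
            d = (back + k) % 8
            nr, nc = cur[0] + _NBRS[d][0], cur[1] + _NBRS[d][1]
            if at(nr, nc):
                # the empty cell scanned just before d, seen from the new pixel
                er, ec = cur[0] + _NBRS[(d - 1) % 8][0], cur[1] + _NBRS[(d - 1) % 8][1]
                back = _NBRS.index((er - nr, ec - nc))
                cur = (nr, nc)
                break
        else:  # isolated pixel; unreachable after the single-pixel guard
            break
    return np.array(contour, dtype=int)


def segment_series(series: CineSeries, landmarks: LandmarkSet,
                   params: SegmentationParams | None = None) -> MaskStack:
    """Reference segmentation followed by propagation: the full stack."""
    params = params or SegmentationParams()
    ref = landmarks.reference_frame
    ref_mask = segment_reference(series.frames[ref], landmarks, params)
    return propagate(series, ref_mask, params, reference_frame=ref)
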