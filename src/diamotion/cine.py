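"""Cine-series and landmark containers plus file readers.

Conventions
-----------
Frames are stored as a ``(n_frames, n_rows, n_cols)`` float array in
0-based ``(row, column)`` pixel coordinates.  Row index increases in the
inferior direction (down the image), column index increases posteriorly,
so the anterior chest wall sits at low column indices.  Series acquired
with the opposite left/right convention are mirrored on load via
``flip_anterior``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["CineSeries", "LandmarkSet", "read_cine", "read_landmarks", "write_cine"]


@dataclass
class CineSeries:
    """A time-ordered stack of 2-D frames from a single-slice dynamic scan.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, n_rows, n_cols)
        Image intensities, arbitrary units.
    pixel_spacing : float
        Isotropic in-plane pixel size in mm.
    frame_interval : float
        Time between successive frames in seconds.
    flip_anterior : bool
        True if the stored frames were mirrored so that anterior is at
        low column index (bookkeeping only; mirroring happens on load).
    """

    frames: np.ndarray
    pixel_spacing: float
    frame_interval: float
    flip_anterior: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"expected a (frames, rows, cols) stack, got shape {self.frames.shape}"
            )
        if self.n_frames < 2:
            raise ValueError("a cine series needs at least 2 frames")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive (mm)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (s)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of a single frame."""
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class LandmarkSet:
    """Three user-placed reference points on one frame.

    ``anterior`` marks the anterior chest-wall margin, ``central`` the
    tracheal bifurcation (carina), ``posterior`` the posterior chest-wall
    margin; each is a ``(row, column)`` pixel coordinate.
    """

    anterior: tuple[int, int]
    central: tuple[int, int]
    posterior: tuple[int, int]
    reference_frame: int = 0

    def __post_init__(self) -> None:
        if not (self.anterior[1] < self.central[1] < self.posterior[1]):
            raise ValueError(
                "landmark columns must be ordered anterior < central < posterior, got "
                f"{self.anterior[1]}, {self.central[1]}, {self.posterior[1]}"
            )

    @property
    def columns(self) -> tuple[int, int, int]:
        return (self.anterior[1], self.central[1], self.posterior[1])

    @property
    def centroid(self) -> tuple[float, float]:
        pts = np.array([self.anterior, self.central, self.posterior], dtype=float)
        r, c = pts.mean(axis=0)
        return (float(r), float(c))

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        for name in ("anterior", "central", "posterior"):
            r, c = getattr(self, name)
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(
                    f"{name} landmark ({r}, {c}) is outside the {rows}x{cols} image"
                )

    def flipped(self, n_cols: int) -> "LandmarkSet":
        """Mirror the landmark columns for a column-flipped series."""
        flip = lambda p: (p[0], n_cols - 1 - p[1])
        return LandmarkSet(flip(self.posterior), flip(self.central), flip(self.anterior),
                           self.reference_frame)


def read_cine(path: str | Path, *, pixel_spacing: float | None = None,
              frame_interval: float | None = None,
              flip_anterior: bool = False) -> CineSeries:
    """Read a 2-D+time series from NIfTI or multi-page TIFF.

    NIfTI files carry pixel spacing and frame interval in the header
    (zooms); explicit keyword values override the header with a logged
    warning.  TIFF files carry no trusted spacing, so explicit values
    are required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cine series not found: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(
                f"expected a 2-D+time NIfTI (rows, cols, frames), got shape {data.shape}"
            )
        frames = np.moveaxis(data, -1, 0).astype(float)
        zooms = img.header.get_zooms()
        hdr_spacing = float(zooms[0]) if len(zooms) >= 2 else 0.0
        hdr_interval = float(zooms[2]) if len(zooms) >= 3 else 0.0
        if pixel_spacing is not None and hdr_spacing > 0 and pixel_spacing != hdr_spacing:
            logger.warning(
                "config pixel_spacing %.4g mm overrides header %.4g mm", pixel_spacing,
                hdr_spacing)
        if frame_interval is not None and hdr_interval > 0 and frame_interval != hdr_interval:
            logger.warning(
                "config frame_interval %.4g s overrides header %.4g s", frame_interval,
                hdr_interval)
        spacing = pixel_spacing if pixel_spacing is not None else hdr_spacing
        interval = frame_interval if frame_interval is not None else hdr_interval
        if spacing <= 0:
            raise ValueError("no usable pixel spacing in header; pass pixel_spacing")
        if interval <= 0:
            raise ValueError("no usable frame interval in header; pass frame_interval")
    elif suffixes.endswith((".tif", ".tiff")):
        frames = tifffile.imread(str(path)).astype(float)
        if frames.ndim == 2:
            raise ValueError(
                f"expected a multi-page TIFF (frames, rows, cols), got a single page "
                f"of shape {frames.shape}")
        if frames.ndim != 3:
            raise ValueError(f"expected a 3-D TIFF stack, got shape {frames.shape}")
        if pixel_spacing is None:
            raise ValueError("TIFF input carries no pixel spacing; pass pixel_spacing")
        if frame_interval is None:
            raise ValueError("TIFF input carries no frame interval; pass frame_interval")
        spacing, interval = pixel_spacing, frame_interval
    else:
        raise ValueError(f"unsupported cine format: {path.name} (use NIfTI or TIFF)")

    if flip_anterior:
        frames = frames[:, :, ::-1].copy()
    return CineSeries(frames, float(spacing), float(interval), flip_anterior)


def write_cine(series: CineSeries, path: str | Path) -> Path:
    """Write a series as NIfTI (time on the 3rd axis) or multi-page TIFF."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        data = np.moveaxis(series.frames, 0, -1)
        img = nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4))
        img.header.set_zooms((series.pixel_spacing, series.pixel_spacing,
                              series.frame_interval))
        nib.save(img, str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        tifffile.imwrite(str(path), series.frames.astype(np.float32))
    else:
        raise ValueError(f"unsupported cine format: {path.name} (use NIfTI or TIFF)")
    return path


def read_landmarks(path: str | Path,
                   image_shape: tuple[int, int] | None = None) -> LandmarkSet:
    """Read the three initialization points from a JSON file.

    Expected schema::

        {"anterior": [row, col], "central": [row, col],
         "posterior": [row, col], "frame": 0}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"landmarks file not found: {path}")
    with open(path) as fh:
        raw = json.load(fh)
    points = {}
    for name in ("anterior", "central", "posterior"):
        if name not in raw:
            raise ValueError(f"landmarks file {path} is missing the '{name}' point")
        pt = raw[name]
        if len(pt) != 2:
            raise ValueError(f"'{name}' must be a [row, col] pair, got {pt!r}")
        r, c = int(pt[0]), int(pt[1])
        if r < 0 or c < 0:
            raise ValueError(f"'{name}' point ({r}, {c}) has a negative coordinate")
        points[name] = (r, c)
    lm = LandmarkSet(points["anterior"], points["central"], points["posterior"],
                     reference_frame=int(raw.get("frame", 0)))
    if image_shape is not None:
        lm.validate_bounds(image_shape)
    return lm


def write_landmarks(lm: LandmarkSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"anterior": list(lm.anterior), "central": list(lm.central),
                   "posterior": list(lm.posterior), "frame": lm.reference_frame},
                  fh, indent=2)
        fh.write("\n")
    return path
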