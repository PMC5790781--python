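"""Synthetic sagittal breathing-lung phantom with analytic ground truth.

The phantom emulates a single-slice right-sagittal dynamic scan during
instructed deep breathing: a dark lung cross-section on bright tissue,
whose flat superior boundary sits at ``apex_row`` and whose inferior
boundary (the diaphragm) is a parabolic dome passing through three
control points at the anterior chest-wall margin, the carina column and
the posterior chest-wall margin.  Each control length follows a raised
cosine between its end-expiration (``length_min``) and end-inspiration
(``length_max``) values; independent phase lags per control point
introduce regional dyssynchrony of diaphragm motion.

Because the central column is constrained to the midpoint of the margin
columns, the dome is a parabola and Simpson's rule gives the enclosed
area exactly, so the ground-truth cross-sectional area (CSA) has a
closed form against which raster-based measurements can be validated.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cine import CineSeries, LandmarkSet
from .measures import FrameMeasurement, MeasurementProfile

__all__ = [
    "PhantomSpec", "PhantomTruth", "control_length", "truth_csa",
    "generate_phantom", "phantom_landmarks", "PRESETS", "preset_spec",
]

_POINT_NAMES = ("anterior", "central", "posterior")

# End-expiration / end-inspiration control lengths (mm) programmed from
# published group means for healthy-control and DMD cohorts.
PRESETS: dict[str, dict] = {
    "control": {
        "length_min": (172.6, 146.2, 182.6),
        "length_max": (211.0, 217.3, 258.0),
    },
    "dmd": {
        "length_min": (96.9, 86.8, 115.7),
        "length_max": (129.2, 130.5, 171.2),
    },
}


@dataclass
class PhantomSpec:
    """Full parameterization of a synthetic cine series.

    Geometry is in 0-based (row, column) pixels, row increasing
    inferiorly and column increasing posteriorly; lengths are mm, times
    seconds.  ``central_column`` must be the midpoint of the margin
    columns so the Simpson closed form for the truth CSA is exact.
    """

    image_height: int = 160
    image_width: int = 100
    pixel_spacing: float = 2.0          # mm/pixel, isotropic
    n_frames: int = 60
    frame_interval: float = 0.5         # s
    anterior_column: int = 20
    central_column: int = 50
    posterior_column: int = 80
    apex_row: int = 10
    length_min: tuple[float, float, float] = PRESETS["control"]["length_min"]
    length_max: tuple[float, float, float] = PRESETS["control"]["length_max"]
    breathing_frequency: float = 0.1    # Hz; 3 deep breaths over a 30 s series
    phase_lag: tuple[float, float, float] = (0.0, 0.0, 0.0)   # radians
    lung_intensity: float = 30.0
    tissue_intensity: float = 200.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.anterior_column < self.central_column < self.posterior_column):
            raise ValueError("columns must satisfy anterior < central < posterior")
        if 2 * self.central_column != self.anterior_column + self.posterior_column:
            raise ValueError(
                "central_column must be the midpoint of the margin columns "
                "(Simpson closed form for truth CSA is otherwise invalid)")
        self.length_min = tuple(float(v) for v in self.length_min)
        self.length_max = tuple(float(v) for v in self.length_max)
        self.phase_lag = tuple(float(v) for v in self.phase_lag)
        for lo, hi in zip(self.length_min, self.length_max):
            if not (hi >= lo >= 0.0):
                raise ValueError("need length_max >= length_min >= 0 per control point")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.frame_interval <= 0 or self.breathing_frequency <= 0:
            raise ValueError("frame_interval and breathing_frequency must be positive")

    @property
    def duration(self) -> float:
        """Time of the last sampled frame, s."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def width_mm(self) -> float:
        """Anterior-to-posterior span between the margin columns, mm."""
        return (self.posterior_column - self.anterior_column) * self.pixel_spacing

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class PhantomTruth:
    """Analytic ground truth emitted alongside a synthetic series."""

    truth_profile: MeasurementProfile
    truth_masks: np.ndarray             # (n_frames, rows, cols) bool
    control_lengths: np.ndarray         # (n_frames, 3) mm


def _point_index(point: int | str) -> int:
    if isinstance(point, str):
        try:
            return _POINT_NAMES.index(point)
        except ValueError:
            raise ValueError(f"unknown control point {point!r}") from None
    if point not in (0, 1, 2):
        raise ValueError(f"control point index must be 0, 1 or 2, got {point}")
    return point


def control_length(spec: PhantomSpec, point: int | str, t: float | np.ndarray):
    """Length of one control point at time ``t`` (s), in mm.

    Raised-cosine deep-breathing waveform starting at end-expiration:
    ``L(t) = min + (max - min) * (1 - cos(2*pi*f*t + phase)) / 2``.
    """
    i = _point_index(point)
    lo, hi = spec.length_min[i], spec.length_max[i]
    phase = 2.0 * np.pi * spec.breathing_frequency * np.asarray(t, dtype=float)
    out = lo + (hi - lo) * (1.0 - np.cos(phase + spec.phase_lag[i])) / 2.0
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def _parabola_lengths(spec: PhantomSpec, columns: np.ndarray, t: float) -> np.ndarray:
    """Dome depth (mm below the apex) at arbitrary columns, time ``t``."""
    la = control_length(spec, 0, t)
    lc = control_length(spec, 1, t)
    lp = control_length(spec, 2, t)
    h = spec.central_column - spec.anterior_column
    u = (np.asarray(columns, dtype=float) - spec.central_column) / h
    return lc + u * (lp - la) / 2.0 + u ** 2 * (la + lp - 2.0 * lc) / 2.0


def truth_csa(spec: PhantomSpec, t: float) -> float:
    """Closed-form lung cross-sectional area at time ``t``, in cm².

    The inferior boundary is the parabola through the three control
    points, so Simpson's rule over the margin-to-margin span is exact:
    ``CSA = width/6 * (L_ant + 4*L_cnt + L_pst)``.
    """
    la = control_length(spec, 0, t)
    lc = control_length(spec, 1, t)
    lp = control_length(spec, 2, t)
    area_mm2 = spec.width_mm / 6.0 * (la + 4.0 * lc + lp)
    return area_mm2 / 100.0


def _truth_dome_arc(spec: PhantomSpec, t: float, n_samples: int = 4097) -> float:
    """Arc length (mm) of the parabolic dome between the margin columns."""
    x_mm = np.linspace(spec.anterior_column, spec.posterior_column, n_samples)
    y_mm = _parabola_lengths(spec, x_mm, t)
    x_mm = x_mm * spec.pixel_spacing
    return float(np.hypot(np.diff(x_mm), np.diff(y_mm)).sum())


def _rasterize(spec: PhantomSpec, t: float, frame_idx: int) -> np.ndarray:
    """Binary lung mask for one frame; pixel centers inside the dome."""
    cols = np.arange(spec.anterior_column, spec.posterior_column + 1)
    depth_mm = _parabola_lengths(spec, cols, t)
    # pixel (r, col) is lung iff its center lies within depth of the apex row
    n_px = np.floor(depth_mm / spec.pixel_spacing + 0.5).astype(int)
    bottom = spec.apex_row + n_px - 1
    if np.any(bottom >= spec.image_height):
        bad = cols[np.argmax(bottom)]
        raise ValueError(
            f"phantom geometry exceeds image bounds at frame {frame_idx}, "
            f"column {bad}: dome reaches row {int(bottom.max())} "
            f">= image_height {spec.image_height}")
    mask = np.zeros((spec.image_height, spec.image_width), dtype=bool)
    for c, b in zip(cols, bottom):
        if b >= spec.apex_row:
            mask[spec.apex_row:b + 1, c] = True
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[CineSeries, PhantomTruth]:
    """Render the synthetic series and its analytic ground truth.

    The image stack is the rasterized lung (``lung_intensity``) on
    tissue (``tissue_intensity``) with additive zero-mean Gaussian noise
    of ``noise_sigma`` drawn from ``numpy.random.default_rng(seed)``.
    The truth profile is computed analytically from the waveforms, not
    from the raster, so it is an independent oracle for the pipeline.
    """
    times = spec.frame_times
    lengths = np.column_stack([control_length(spec, i, times) for i in range(3)])

    masks = np.stack([_rasterize(spec, t, k) for k, t in enumerate(times)])
    frames = np.where(masks, spec.lung_intensity, spec.tissue_intensity).astype(float)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    series = CineSeries(frames, spec.pixel_spacing, spec.frame_interval)

    # attachments: deepest excursion at each margin over the sampled frames
    deep_ant = float(lengths[:, 0].max())
    deep_pst = float(lengths[:, 2].max())
    measurements = []
    for k, t in enumerate(times):
        ant, cnt, pst = lengths[k]
        dia = (_truth_dome_arc(spec, t)
               + (deep_ant - ant) + (deep_pst - pst))
        measurements.append(FrameMeasurement(
            frame=k, time=float(t), csa=truth_csa(spec, t),
            ant=float(ant), cnt=float(cnt), pst=float(pst),
            tdm=float(ant + cnt + pst), dia=dia, valid=True))
    profile = MeasurementProfile(measurements, pixel_spacing=spec.pixel_spacing,
                                 frame_interval=spec.frame_interval)
    return series, PhantomTruth(profile, masks, lengths)


def phantom_landmarks(spec: PhantomSpec, depth: int = 5) -> LandmarkSet:
    """Canonical landmark placement for a phantom: margin and carina
    columns, a few rows below the lung apex on frame 0."""
    row = spec.apex_row + depth
    return LandmarkSet((row, spec.anterior_column), (row, spec.central_column),
                       (row, spec.posterior_column), reference_frame=0)


def preset_spec(name: str, **overrides) -> PhantomSpec:
    """A :class:`PhantomSpec` for the 'control' or 'dmd' preset."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)
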