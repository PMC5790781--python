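"""Model/results interface over the full analysis pipeline.

:class:`DiaphragmMotion` bundles a cine series with its landmark set
(the one manual input of the method); :meth:`DiaphragmMotion.fit` runs
segmentation, per-frame measurement and the length-vs-CSA regressions
and returns a :class:`DiaphragmMotionResults` carrying the profile,
the temporal summary measures, the regression fits and segmentation
diagnostics, with ``summary()``, plotting and file export attached.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .cine import CineSeries, LandmarkSet, read_cine, read_landmarks
from .config import AnalysisConfig
from .measures import (MEASURES, MeasurementProfile, SummaryMeasures,
                       build_profile, summarize)
from .output import plot_profiles, qc_animation, regressions_to_frame, write_outputs
from .segmentation import MaskStack, SegmentationParams, segment_series
from .stats import RegressionFit, length_vs_csa

logger = logging.getLogger(__name__)

__all__ = ["DiaphragmMotion", "DiaphragmMotionResults", "run_analyze"]


class DiaphragmMotion:
    """Diaphragm-motion analysis of one cine series.

    Parameters
    ----------
    series : CineSeries
        The 2-D+time image stack.
    landmarks : LandmarkSet
        Anterior-margin, carina and posterior-margin points on the
        reference frame; they seed the segmentation and fix the three
        length-measurement columns.
    seg_params : SegmentationParams, optional
        Segmentation tuning; defaults are parameter-free apart from
        the per-frame Otsu threshold.
    """

    def __init__(self, series: CineSeries, landmarks: LandmarkSet,
                 seg_params: SegmentationParams | None = None):
        landmarks.validate_bounds(series.shape)
        if not 0 <= landmarks.reference_frame < series.n_frames:
            raise ValueError(f"reference frame {landmarks.reference_frame} outside "
                             f"series of {series.n_frames} frames")
        self.series = series
        self.landmarks = landmarks
        self.seg_params = seg_params or SegmentationParams()

    @classmethod
    def from_files(cls, series_path: str | Path, landmarks_path: str | Path,
                   config: AnalysisConfig | None = None) -> "DiaphragmMotion":
        """Build the model from a NIfTI/TIFF series and a landmark JSON."""
        config = config or AnalysisConfig()
        series = read_cine(series_path, pixel_spacing=config.pixel_spacing,
                           frame_interval=config.frame_interval,
                           flip_anterior=config.flip_anterior)
        landmarks = read_landmarks(landmarks_path, image_shape=series.shape)
        if config.flip_anterior:
            landmarks = landmarks.flipped(series.shape[1])
        return cls(series, landmarks, seg_params=config.segmentation)

    def fit(self) -> "DiaphragmMotionResults":
        """Segment every frame, measure, summarize and regress."""
        logger.info("segmenting %d frames (%s)", self.series.n_frames,
                    self.seg_params)
        mask_stack = segment_series(self.series, self.landmarks, self.seg_params)
        profile = build_profile(self.series, mask_stack, self.landmarks)
        summary = summarize(profile)
        regressions = length_vs_csa(profile)
        return DiaphragmMotionResults(self, mask_stack, profile, summary,
                                      regressions)


class DiaphragmMotionResults:
    """Fitted results: profile, summaries, regressions, diagnostics."""

    def __init__(self, model: DiaphragmMotion, mask_stack: MaskStack,
                 profile: MeasurementProfile, summary_measures: SummaryMeasures,
                 regressions: dict[str, RegressionFit]):
        self.model = model
        self.mask_stack = mask_stack
        self.profile = profile
        self.summary_measures = summary_measures
        self.regressions = regressions

    @property
    def n_valid_frames(self) -> int:
        return self.profile.n_valid

    def profile_frame(self) -> pd.DataFrame:
        return self.profile.to_frame()

    def summary_frame(self) -> pd.DataFrame:
        return self.summary_measures.to_frame()

    def regressions_frame(self) -> pd.DataFrame:
        return regressions_to_frame(self.regressions)

    def summary(self) -> str:
        """Human-readable result table."""
        s = self.summary_measures
        lines = [
            "Diaphragm motion analysis".center(72),
            "=" * 72,
            f"frames: {len(self.profile)} total, {self.n_valid_frames} valid"
            f"   pixel spacing: {self.model.series.pixel_spacing:g} mm"
            f"   frame interval: {self.model.series.frame_interval:g} s",
            "-" * 72,
            f"{'measure':>8} {'min':>10} {'max':>10} {'delta':>10} "
            f"{'mean':>10} {'SD':>10}",
        ]
        units = {"CSA": "cm2"}
        for m in MEASURES:
            st = s[m]
            unit = units.get(m, "mm")
            lines.append(f"{m + ' ' + unit:>8} {st.min:>10.2f} {st.max:>10.2f} "
                         f"{st.delta:>10.2f} {st.mean:>10.2f} {st.sd:>10.2f}")
        lines += [
            "-" * 72,
            "length vs CSA regressions (slope S mm/cm2, intercept C mm)",
            f"{'measure':>8} {'S':>10} {'C':>10} {'R':>10} {'p':>12} {'n':>6}",
        ]
        for name, fit in self.regressions.items():
            lines.append(f"{name:>8} {fit.slope:>10.4f} {fit.intercept:>10.2f} "
                         f"{fit.r:>10.4f} {fit.p_value:>12.3e} {fit.n:>6d}")
        lines.append("=" * 72)
        return "\n".join(lines)

    def plot_profiles(self, path: str | Path | None = None):
        return plot_profiles(self.profile, path)

    def qc_animation(self, path: str | Path) -> Path:
        return qc_animation(self.model.series, self.mask_stack,
                            self.model.landmarks, path)

    def save(self, out_dir: str | Path, qc: bool = True) -> dict[str, Path]:
        """Write the CSV/PNG/GIF output bundle."""
        return write_outputs(
            self.profile, self.summary_measures, self.regressions, out_dir,
            series=self.model.series if qc else None,
            mask_stack=self.mask_stack if qc else None,
            landmarks=self.model.landmarks if qc else None)


def run_analyze(series_path: str | Path, landmarks_path: str | Path,
                out_dir: str | Path, config: AnalysisConfig | str | Path | None = None,
                dry_run: bool = False) -> int:
    """End-to-end pipeline: read, segment, measure, summarize, regress,
    write outputs.  Returns 0 on success, nonzero on any stage failure
    (the failing stage is named in the log)."""
    stage = "configuration"
    try:
        if isinstance(config, (str, Path)):
            config = AnalysisConfig.from_yaml(config)
        config = config or AnalysisConfig()
        stage = "input"
        model = DiaphragmMotion.from_files(series_path, landmarks_path, config)
        if dry_run:
            logger.info("dry run: inputs valid (%d frames, landmarks %s); "
                        "nothing written", model.series.n_frames,
                        model.landmarks.columns)
            return 0
        stage = "analysis"
        results = model.fit()
        stage = "output"
        paths = results.save(out_dir)
        logger.info("diamotion %s: wrote %s", _version,
                    ", ".join(str(p) for p in paths.values()))
        return 0
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        logger.error("%s stage failed: %s", stage, exc)
        return 1
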