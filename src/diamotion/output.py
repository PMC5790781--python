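"""Result tables, temporal-variation plots and QC overlay animation."""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

import imageio.v2 as imageio
import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cine import CineSeries, LandmarkSet
from .measures import MeasurementProfile, SummaryMeasures

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import MaskStack
    from .stats import RegressionFit

__all__ = ["regressions_to_frame", "write_outputs", "plot_profiles", "qc_animation"]

_CHORD_COLORS = {"anterior": (220, 60, 60), "central": (60, 200, 60),
                 "posterior": (70, 110, 240)}


def regressions_to_frame(regressions: dict[str, "RegressionFit"]) -> pd.DataFrame:
    """Regression fits as a tidy table (one row per measure)."""
    rows = []
    for name, fit in regressions.items():
        rows.append({"measure": name, "n": fit.n,
                     "slope_mm_per_cm2": fit.slope, "intercept_mm": fit.intercept,
                     "r": fit.r, "abs_r": fit.abs_r, "p_value": fit.p_value})
    return pd.DataFrame(rows)


def plot_profiles(profile: MeasurementProfile, path: str | Path | None = None):
    """Temporal-variation plot: CSA (top) and the five lengths (bottom)."""
    df = profile.to_frame()
    t = df["time_s"]
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    ax1.plot(t, df["CSA_cm2"], "k.-", lw=1)
    ax1.set_ylabel("CSA (cm$^2$)")
    ax1.set_title("Temporal variation of lung and diaphragm measures")
    for col, label in [("ANT_mm", "ANT"), ("CNT_mm", "CNT"), ("PST_mm", "PST"),
                       ("TDM_mm", "TDM"), ("DIA_mm", "DIA")]:
        ax2.plot(t, df[col], ".-", lw=1, label=label)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("length (mm)")
    ax2.legend(ncol=5, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return Path(path)
    return fig


def _overlay_frame(frame: np.ndarray, mask: np.ndarray | None,
                   contour: np.ndarray | None, columns: tuple[int, int, int],
                   lo: float, hi: float) -> np.ndarray:
    """One RGB QC frame: grayscale image + contour + three length chords."""
    g = np.clip((frame - lo) / (hi - lo + 1e-12), 0.0, 1.0)
    rgb = np.repeat((g * 255).astype(np.uint8)[:, :, None], 3, axis=2)
    if contour is not None and len(contour) > 0:
        rgb[contour[:, 0], contour[:, 1]] = (255, 220, 40)
    if mask is not None:
        for name, col in zip(("anterior", "central", "posterior"), columns):
            rows = np.flatnonzero(mask[:, col])
            if rows.size:
                rgb[rows[0]:rows[-1] + 1, col] = _CHORD_COLORS[name]
    return rgb


def qc_animation(series: CineSeries, mask_stack: "MaskStack",
                 landmarks: LandmarkSet, path: str | Path,
                 fps: float | None = None) -> Path:
    """GIF with the lung contour and the three length chords drawn on
    every frame (invalid frames are shown without overlay)."""
    lo, hi = float(series.frames.min()), float(series.frames.max())
    cols = landmarks.columns
    frames = []
    for k in range(series.n_frames):
        mask = mask_stack.masks[k] if mask_stack.valid[k] else None
        contour = mask_stack.contours[k]
        frames.append(_overlay_frame(series.frames[k], mask, contour, cols, lo, hi))
    duration = series.frame_interval if fps is None else 1.0 / fps
    imageio.mimsave(str(path), frames, duration=duration, loop=0)
    return Path(path)


def write_outputs(profile: MeasurementProfile, summary: SummaryMeasures,
                  regressions: dict[str, "RegressionFit"], out_dir: str | Path,
                  series: CineSeries | None = None,
                  mask_stack: "MaskStack | None" = None,
                  landmarks: LandmarkSet | None = None) -> dict[str, Path]:
    """Write the standard output bundle into ``out_dir``.

    Always writes ``profile.csv`` (one row per frame, fixed column
    order), ``summary.csv`` (one wide row) and ``regressions.csv``,
    plus the temporal-variation PNG.  When the series, mask stack and
    landmarks are supplied, the QC overlay GIF is written too.
    Reruns on identical inputs produce byte-identical CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["profile"] = out_dir / "profile.csv"
    profile.to_frame().to_csv(paths["profile"], index=False)
    paths["summary"] = out_dir / "summary.csv"
    summary.to_frame().to_csv(paths["summary"], index=False)
    paths["regressions"] = out_dir / "regressions.csv"
    regressions_to_frame(regressions).to_csv(paths["regressions"], index=False)
    paths["plot"] = plot_profiles(profile, out_dir / "profile_plot.png")
    if series is not None and mask_stack is not None and landmarks is not None:
        paths["qc"] = qc_animation(series, mask_stack, landmarks, out_dir / "qc.gif")
    return paths
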