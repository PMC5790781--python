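"""YAML analysis configuration.

Acquisition defaults mirror the intended protocol (2.0 mm isotropic
in-plane pixels, 0.5 s per frame, ~60 frames); explicit config values
override file headers, with a logged warning when both disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import SegmentationParams

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    pixel_spacing: float | None = None      # mm; None = trust the file header
    frame_interval: float | None = None     # s;  None = trust the file header
    flip_anterior: bool = False
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        acq = raw.get("acquisition", {})
        seg = raw.get("segmentation", {})
        return cls(
            pixel_spacing=acq.get("pixel_spacing_mm"),
            frame_interval=acq.get("frame_interval_s"),
            flip_anterior=bool(acq.get("flip_anterior", False)),
            segmentation=SegmentationParams(**seg),
        )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "acquisition": {
                "pixel_spacing_mm": self.pixel_spacing,
                "frame_interval_s": self.frame_interval,
                "flip_anterior": self.flip_anterior,
            },
            "segmentation": {
                "lung_is_dark": self.segmentation.lung_is_dark,
                "min_overlap": self.segmentation.min_overlap,
                "closing_size": self.segmentation.closing_size,
                "max_invalid_fraction": self.segmentation.max_invalid_fraction,
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        return path
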