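"""Desk-scale reproducibility experiments on phantom data.

These routines emulate, on synthetic subjects, the reliability and
synchrony analyses that on real data require a patient cohort: the
intra-/inter-observer landmark-jitter study and the synchronized vs
phase-lagged regression comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cine import LandmarkSet
from .model import DiaphragmMotion
from .phantom import PhantomSpec, generate_phantom, phantom_landmarks, preset_spec
from .stats import ObserverVariability, observer_variability

__all__ = ["jittered_landmarks", "default_observer_subjects",
           "simulate_observer_study", "ObserverStudyResult"]


def jittered_landmarks(spec: PhantomSpec, rng: np.random.Generator,
                       amplitude: int = 2) -> LandmarkSet:
    """Landmarks perturbed like a human observer's repeat placement.

    Rows and the central (carina) column jitter uniformly over
    ``±amplitude`` px.  The margin-landmark columns jitter inward only
    (uniform over ``{0..amplitude}`` toward the lung): the phantom's
    lung ends exactly at the margin columns, so an outward click would
    fall off the lung and be rejected by the pipeline rather than
    absorbed as observer noise.
    """
    base = phantom_landmarks(spec)
    dr = lambda: int(rng.integers(-amplitude, amplitude + 1))
    anterior = (base.anterior[0] + dr(),
                base.anterior[1] + int(rng.integers(0, amplitude + 1)))
    central = (base.central[0] + dr(), base.central[1] + dr())
    posterior = (base.posterior[0] + dr(),
                 base.posterior[1] - int(rng.integers(0, amplitude + 1)))
    return LandmarkSet(anterior, central, posterior,
                       reference_frame=base.reference_frame)


def default_observer_subjects() -> dict[str, PhantomSpec]:
    """Three synthetic test subjects: a healthy-control geometry, a DMD
    geometry, and an intermediate one (control lengths scaled 0.9)."""
    control = preset_spec("control")
    return {
        "control": control,
        "dmd": preset_spec("dmd"),
        "intermediate": preset_spec(
            "control",
            length_min=tuple(0.9 * np.array(control.length_min)),
            length_max=tuple(0.9 * np.array(control.length_max))),
    }


@dataclass
class ObserverStudyResult:
    summary_table: pd.DataFrame       # one row per observer x subject x repeat
    variability: ObserverVariability

    @property
    def max_cv_per_measure(self) -> pd.Series:
        return self.variability.cv_table.groupby("measure")["cv_pct"].max()


def simulate_observer_study(subjects: dict[str, PhantomSpec] | None = None,
                            n_observers: int = 2, n_repeats: int = 5,
                            jitter_px: int = 2, seed: int = 0) -> ObserverStudyResult:
    """Run the landmark-jitter observer study on phantom subjects.

    Each simulated observer re-places the three landmarks
    ``n_repeats`` times per subject with ``±jitter_px`` error and the
    full pipeline is rerun; the pipeline itself is deterministic, so
    all run-to-run variation comes from the landmarks, as in the real
    protocol.  Returns the per-run minimum-length summary rows and the
    %CV / rank-sum analysis.
    """
    subjects = subjects or default_observer_subjects()
    series_cache = {name: generate_phantom(spec)[0]
                    for name, spec in subjects.items()}
    rows = []
    for obs_idx in range(n_observers):
        rng = np.random.default_rng(seed * 1000 + obs_idx)
        for name, spec in subjects.items():
            series = series_cache[name]
            for rep in range(n_repeats):
                lm = jittered_landmarks(spec, rng, jitter_px)
                summary = DiaphragmMotion(series, lm).fit().summary_measures
                row = {"observer": f"observer{obs_idx + 1}", "subject": name,
                       "repeat": rep}
                for m in ("ANT", "CNT", "PST", "DIA"):
                    row[f"{m}_min"] = summary[m].min
                rows.append(row)
    table = pd.DataFrame(rows)
    return ObserverStudyResult(table, observer_variability(table))
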