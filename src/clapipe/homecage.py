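"""Circadian relative amplitude and activity-bout statistics for
binned home-cage activity-index series.

The activity index is an arbitrary-unit readout of in-cage movement
(capacitive-sensor based in the original platform). Relative amplitude
contrasts mean activity between the dark and light phases of the 12 h
light cycle:

    RA = (AI_D - AI_L) / (AI_D + AI_L)

so RA is 1 for a purely dark-active animal, 0 for no day/night
contrast, and negative for light-active animals. Activity bouts are
maximal runs of bins at or above a 0.2 a.u. threshold; sub-threshold
gaps shorter than 1 min are merged into the surrounding bout before
runs shorter than 1 min are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BOUT_THRESHOLD = 0.2
BOUT_MIN_DURATION_S = 60.0
BOUT_MIN_GAP_S = 60.0


@dataclass
class ActivitySeries:
    """Uniformly binned activity index with light/dark phase labels.

    Phase of a bin straddling a light transition is assigned by the bin
    start time.
    """

    start_s: np.ndarray
    activity: np.ndarray
    phase: np.ndarray  # "light" or "dark" per bin
    bin_width_s: float

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not self.start_s.shape == self.activity.shape == self.phase.shape:
            raise ValueError("start_s, activity and phase must align")
        if np.any(self.activity < 0):
            raise ValueError("activity index must be >= 0")
        if not set(self.phase) <= {"light", "dark"}:
            raise ValueError("phase labels must be 'light' or 'dark'")
        if self.bin_width_s <= 0:
            raise ValueError("bin_width_s must be > 0")
        if self.start_s.size > 1:
            widths = np.diff(self.start_s)
            if not np.allclose(widths, self.bin_width_s):
                raise ValueError("bins must be uniform")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_start_s": self.start_s, "activity_index": self.activity,
             "phase": self.phase}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ActivitySeries":
        start = df["bin_start_s"].to_numpy(dtype=float)
        width = float(start[1] - start[0]) if start.size > 1 else 60.0
        return cls(start, df["activity_index"].to_numpy(dtype=float),
                   df["phase"].to_numpy(dtype=object), width)


def relative_amplitude(series: ActivitySeries) -> float | None:
    """Circadian relative amplitude, ``(AI_D - AI_L) / (AI_D + AI_L)``.

    ``AI_D`` and ``AI_L`` are the mean activity index over dark and
    light bins. Undefined (None) when both phase means are zero; raises
    if either phase is absent from the series.
    """
    dark = series.activity[series.phase == "dark"]
    light = series.activity[series.phase == "light"]
    if dark.size == 0 or light.size == 0:
        raise ValueError("both light and dark phases must be present")
    ai_d, ai_l = float(dark.mean()), float(light.mean())
    if ai_d + ai_l == 0:
        return None
    return (ai_d - ai_l) / (ai_d + ai_l)


def detect_bouts(
    series: ActivitySeries,
    threshold: float = BOUT_THRESHOLD,
    min_duration_s: float = BOUT_MIN_DURATION_S,
    min_gap_s: float = BOUT_MIN_GAP_S,
) -> pd.DataFrame:
    """Activity bouts: supra-threshold runs, merge gaps, filter duration.

    A bout is a maximal run of bins whose activity never falls below
    ``threshold``. Runs separated by sub-threshold gaps shorter than
    ``min_gap_s`` are merged (the gap is absorbed into the bout), then
    bouts shorter than ``min_duration_s`` are discarded. Merging
    precedes the duration filter.

    Returns a frame with columns start_s, end_s, duration_s.
    """
    active = series.activity >= threshold
    w = series.bin_width_s
    # maximal runs of active bins as (first_bin, last_bin) inclusive
    runs: list[list[int]] = []
    in_run = False
    for i, a in enumerate(active):
        if a and not in_run:
            runs.append([i, i])
            in_run = True
        elif a:
            runs[-1][1] = i
        else:
            in_run = False
    merged: list[list[int]] = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) * w < min_gap_s:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    rows = []
    for first, last in merged:
        duration = (last - first + 1) * w
        if duration >= min_duration_s:
            rows.append(
                {"start_s": series.start_s[first],
                 "end_s": series.start_s[first] + duration,
                 "duration_s": duration}
            )
    return pd.DataFrame(rows, columns=["start_s", "end_s", "duration_s"])


def bout_summary(bouts: pd.DataFrame) -> dict:
    """Bout count, mean duration and total bout time."""
    n = int(len(bouts))
    return {
        "n_bouts": n,
        "mean_duration_s": float(bouts["duration_s"].mean()) if n else None,
        "total_bout_time_s": float(bouts["duration_s"].sum()),
    }
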