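"""Readers and writers for the pipeline's on-disk formats.

HDF5 holds the dense numeric streams (fluorescence recordings and
sweep sets); CSV holds the tabular ones (stimulus schedules, behavior
event logs, activity series). The schemas round-trip the synthetic
generators losslessly and double as the mapping target for user data.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import BehaviorSession
from .homecage import ActivitySeries
from .imaging import AxonRecording, StimulusSchedule
from .opto import SweepSet


# ---------------------------------------------------------------- HDF5

def write_recording(path, recording: AxonRecording, seed: int | None = None) -> None:
    """Write an axon recording (datasets: fluorescence, neuropil, timebase)."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("fluorescence", data=recording.fluorescence)
        if recording.neuropil is not None:
            h5.create_dataset("neuropil", data=recording.neuropil)
        h5.create_dataset(
            "timebase", data=np.arange(recording.n_frames) / recording.frame_rate
        )
        h5.attrs["rate"] = recording.frame_rate
        if seed is not None:
            h5.attrs["seed"] = seed
        sched = h5.create_group("schedule")
        sched.create_dataset(
            "trial_type",
            data=np.asarray(recording.schedule.trial_types, dtype="S"),
        )
        sched.create_dataset("onset_s", data=recording.schedule.onsets_s)
        sched.attrs["duration_s"] = recording.schedule.duration_s


def read_recording(path) -> AxonRecording:
    with h5py.File(path, "r") as h5:
        schedule = StimulusSchedule(
            np.array([t.decode() for t in h5["schedule/trial_type"][()]], dtype=object),
            h5["schedule/onset_s"][()],
            float(h5["schedule"].attrs["duration_s"]),
        )
        return AxonRecording(
            h5["fluorescence"][()],
            float(h5.attrs["rate"]),
            schedule,
            neuropil=h5["neuropil"][()] if "neuropil" in h5 else None,
        )


def write_sweep_cohort(path, cells: dict[object, dict[object, SweepSet]],
                       seed: int | None = None) -> None:
    """Write per-cell, per-channel sweep sets (group ``cell_<id>/input_<ch>``)."""
    with h5py.File(path, "w") as h5:
        if seed is not None:
            h5.attrs["seed"] = seed
        for cell_id, channels in cells.items():
            cg = h5.create_group(f"cell_{cell_id}")
            for ch, ss in channels.items():
                g = cg.create_group(f"input_{ch}")
                g.create_dataset("sweeps", data=ss.sweeps)
                g.attrs.update(
                    rate=ss.rate, clamp_mode=ss.clamp_mode,
                    stim_onset=ss.stim_onset, stim_offset=ss.stim_offset,
                    input_channel=str(ss.input_channel),
                    simultaneous=ss.simultaneous,
                )


def read_sweep_cohort(path) -> dict[str, dict[str, SweepSet]]:
    cells: dict[str, dict[str, SweepSet]] = {}
    with h5py.File(path, "r") as h5:
        for cell_name in sorted(h5):
            cell_id = cell_name.removeprefix("cell_")
            channels = {}
            for ch_name in sorted(h5[cell_name]):
                g = h5[cell_name][ch_name]
                channels[ch_name.removeprefix("input_")] = SweepSet(
                    g["sweeps"][()],
                    float(g.attrs["rate"]),
                    str(g.attrs["clamp_mode"]),
                    float(g.attrs["stim_onset"]),
                    float(g.attrs["stim_offset"]),
                    input_channel=str(g.attrs["input_channel"]),
                    simultaneous=bool(g.attrs["simultaneous"]),
                )
            cells[cell_id] = channels
    return cells


# ----------------------------------------------------------------- CSV

def write_schedule(path, schedule: StimulusSchedule) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule(path) -> StimulusSchedule:
    return StimulusSchedule.from_frame(pd.read_csv(path))


def write_events(path, session: BehaviorSession) -> None:
    session.events.to_csv(path, index=False)


def read_events(path) -> BehaviorSession:
    return BehaviorSession(pd.read_csv(path))


def write_activity(path, series: ActivitySeries) -> None:
    series.to_frame().to_csv(path, index=False)


def read_activity(path) -> ActivitySeries:
    return ActivitySeries.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------- JSON

def write_report(path, report: dict) -> None:
    """Deterministic JSON report (sorted keys, native types)."""
    Path(path).write_text(json.dumps(_pyify(report), indent=2, sort_keys=True) + "\n")


def _pyify(obj):
    if isinstance(obj, dict):
        return {str(k): _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, np.ndarray):
        return [_pyify(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
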