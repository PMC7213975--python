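"""Readers and writers for the session container and tabular formats.

A session lives in one HDF5 file with groups ``/wheel`` (t, angle),
``/lfp`` (samples; fs and t0 as attributes), ``/spikes/<unit>`` (times,
optional waveform) and, for synthetic sessions only, ``/truth`` holding
the planted ground truth. The analysis readers never touch ``/truth``.

Tabular side formats: wheel traces and trajectories as two/three-column
CSV, segmentations as BED-like (label, start_s, end_s) CSV, cohort tables
as CSV with seizure events in a JSON column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import Trajectory
from .locomotion import StateSegmentation, WheelTrace
from .spectral import LFPSignal
from .stats import AnimalRecord, SeizureEvent
from .units import SpikeTrain, Waveform

__all__ = [
    "SessionData",
    "write_session",
    "read_session",
    "read_wheel_csv",
    "write_segmentation_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "records_to_frame",
    "frame_to_records",
]


@dataclass(frozen=True)
class SessionData:
    """What the pipeline reads from a session container (no ground truth)."""

    wheel: WheelTrace
    lfp: LFPSignal
    spikes: list[SpikeTrain]


def write_session(path: str | Path, session) -> None:
    """Write a session (optionally with ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        gw = f.create_group("wheel")
        gw.create_dataset("t", data=session.wheel.t)
        gw.create_dataset("angle", data=session.wheel.angle)
        gw.attrs["wheel_diameter_cm"] = session.wheel.wheel_diameter_cm
        gl = f.create_group("lfp")
        gl.create_dataset("samples", data=session.lfp.samples)
        gl.attrs["fs"] = session.lfp.fs
        gl.attrs["t0"] = session.lfp.t0
        gs = f.create_group("spikes")
        for train in session.spikes:
            gu = gs.create_group(train.unit_id)
            gu.create_dataset("times", data=train.spike_times)
            if train.waveform is not None:
                gu.create_dataset("waveform", data=train.waveform.samples)
                gu.attrs["waveform_fs"] = train.waveform.fs
        if getattr(session, "true_bouts", None) is not None:
            gt = f.create_group("truth")
            gt.create_dataset("bouts", data=np.asarray(session.true_bouts, dtype=float))
            gt.attrs["rate_q_hz"] = json.dumps(session.true_rate_q)
            gt.attrs["rate_l_hz"] = json.dumps(session.true_rate_l)
            gt.attrs["band_gain"] = json.dumps(session.true_band_gain)
            gt.attrs["seed"] = session.seed


def read_session(path: str | Path) -> SessionData:
    """Read the analysis-facing parts of a session container."""
    with h5py.File(path, "r") as f:
        wheel = WheelTrace(
            t=f["wheel/t"][...],
            angle=f["wheel/angle"][...],
            wheel_diameter_cm=float(f["wheel"].attrs["wheel_diameter_cm"]),
        )
        lfp = LFPSignal(
            fs=float(f["lfp"].attrs["fs"]),
            samples=f["lfp/samples"][...],
            t0=float(f["lfp"].attrs["t0"]),
        )
        spikes = []
        for uid in sorted(f["spikes"]):
            gu = f["spikes"][uid]
            wf = None
            if "waveform" in gu:
                wf = Waveform(samples=gu["waveform"][...], fs=float(gu.attrs["waveform_fs"]))
            spikes.append(SpikeTrain(unit_id=uid, spike_times=gu["times"][...], waveform=wf))
    return SessionData(wheel=wheel, lfp=lfp, spikes=spikes)


def read_session_truth(path: str | Path) -> dict:
    """Ground-truth sidecar of a synthetic session (tests only)."""
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise KeyError("session has no ground-truth group")
        gt = f["truth"]
        return {
            "bouts": [tuple(b) for b in gt["bouts"][...]],
            "rate_q_hz": json.loads(gt.attrs["rate_q_hz"]),
            "rate_l_hz": json.loads(gt.attrs["rate_l_hz"]),
            "band_gain": json.loads(gt.attrs["band_gain"]),
            "seed": int(gt.attrs["seed"]),
        }


def read_wheel_csv(path: str | Path, wheel_diameter_cm: float = 15.0) -> WheelTrace:
    df = pd.read_csv(path)
    return WheelTrace(
        t=df["t_s"].to_numpy(),
        angle=df["angle_rad"].to_numpy(),
        wheel_diameter_cm=wheel_diameter_cm,
    )


def write_segmentation_csv(seg: StateSegmentation, path: str | Path) -> None:
    rows = [(lab, s, e) for lab, s, e in seg.intervals()]
    pd.DataFrame(rows, columns=["label", "start_s", "end_s"]).to_csv(path, index=False)


def read_trajectory_csv(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        t=df["t_s"].to_numpy(), x=df["x_cm"].to_numpy(), y=df["y_cm"].to_numpy()
    )


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"t_s": traj.t, "x_cm": traj.x, "y_cm": traj.y}).to_csv(path, index=False)


def records_to_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "animal_id": r.animal_id,
                "group": r.group,
                "death_age_d": r.death_age_d,
                "censored": r.censored,
                "seizure_events": json.dumps(
                    [[e.age_d, e.racine_level] for e in r.seizure_events]
                ),
            }
        )
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[AnimalRecord]:
    records = []
    for _, row in df.iterrows():
        events = tuple(
            SeizureEvent(age_d=float(a), racine_level=int(lv))
            for a, lv in json.loads(row["seizure_events"])
        )
        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                group=str(row["group"]),
                death_age_d=float(row["death_age_d"]),
                censored=bool(row["censored"]),
                seizure_events=events,
            )
        )
    return records
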