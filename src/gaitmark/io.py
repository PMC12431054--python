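"""CSV/JSON readers and writers for every stream the pipeline touches.

Formats (all plain text):

* IMU:        ``time,gx,gy,gz,ax,ay,az`` + JSON sidecar with fs/placement
* skeleton:   long format ``time,body_id,joint,x,y,z``
* trigger:    ``time,level``
* truth:      ``time,foot,kind,pass``
* events:     ``modality,foot,kind,time``
* windows:    ``label,start,end``
* strides:    one row per stride record
* summary:    ``marker,mean,sd,n``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    EventSeries,
    GaitEvent,
    GroundTruthEvents,
    ImuRecording,
    SkeletonFrame,
    SkeletonRecording,
    StrideRecord,
    SyncSignal,
    TaskWindow,
    TrialSummary,
)

IMU_COLUMNS = ["time", "gx", "gy", "gz", "ax", "ay", "az"]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {', '.join(missing)}")


# ---------------------------------------------------------------------------
# IMU
# ---------------------------------------------------------------------------

def write_imu(rec: ImuRecording, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([rec.t, rec.gyro_xyz, rec.accel_xyz]), columns=IMU_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "fs": rec.fs,
        "placement": rec.placement,
        "axis_convention": rec.axis_convention,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_imu(path: str | Path) -> ImuRecording:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, IMU_COLUMNS, path.name)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ImuRecording(
        fs=float(meta["fs"]),
        t=df["time"].to_numpy(),
        gyro_xyz=df[["gx", "gy", "gz"]].to_numpy(),
        accel_xyz=df[["ax", "ay", "az"]].to_numpy(),
        placement=meta["placement"],
        axis_convention=meta.get("axis_convention", ""),
    )


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------

def write_skeleton(rec: SkeletonRecording, path: str | Path) -> None:
    rows = []
    for fr in rec.frames:
        for joint, (x, y, z) in fr.joints.items():
            rows.append((fr.time, fr.body_id, joint, x, y, z))
    pd.DataFrame(rows, columns=["time", "body_id", "joint", "x", "y", "z"]).to_csv(
        Path(path), index=False, float_format="%.6g"
    )


def read_skeleton(path: str | Path) -> SkeletonRecording:
    df = pd.read_csv(Path(path))
    _require_columns(df, ["time", "body_id", "joint", "x", "y", "z"], Path(path).name)
    frames: list[SkeletonFrame] = []
    for (t, bid), grp in df.groupby(["time", "body_id"], sort=True):
        joints = {
            r.joint: (float(r.x), float(r.y), float(r.z)) for r in grp.itertuples()
        }
        frames.append(SkeletonFrame(time=float(t), body_id=int(bid), joints=joints))
    frames.sort(key=lambda fr: (fr.time, fr.body_id))
    return SkeletonRecording(frames)


# ---------------------------------------------------------------------------
# Trigger / windows
# ---------------------------------------------------------------------------

def write_trigger(sig: SyncSignal, path: str | Path) -> None:
    pd.DataFrame({"time": sig.t, "level": sig.level}).to_csv(
        Path(path), index=False, float_format="%.9g"
    )


def read_trigger(path: str | Path) -> SyncSignal:
    df = pd.read_csv(Path(path))
    _require_columns(df, ["time", "level"], Path(path).name)
    t = df["time"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    return SyncSignal(fs=float(round(fs, 6)), level=df["level"].to_numpy())


def write_windows(windows: list[TaskWindow], path: str | Path) -> None:
    pd.DataFrame(
        [(w.label, w.start, w.end) for w in windows],
        columns=["label", "start", "end"],
    ).to_csv(Path(path), index=False)


def read_windows(path: str | Path) -> list[TaskWindow]:
    df = pd.read_csv(Path(path))
    _require_columns(df, ["label", "start", "end"], Path(path).name)
    return [TaskWindow(r.label, float(r.start), float(r.end)) for r in df.itertuples()]


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def write_truth(truth: GroundTruthEvents, path: str | Path) -> None:
    rows = [(e.time, e.foot, e.kind, e.pass_index) for e in truth.events]
    df = pd.DataFrame(rows, columns=["time", "foot", "kind", "pass"])
    lengths = {i: l for i, l in truth.step_lengths}
    positions = {i: p for i, p in truth.positions}
    df["step_length"] = [lengths.get(i, np.nan) for i in range(len(truth.events))]
    df["position"] = [positions.get(i, np.nan) for i in range(len(truth.events))]
    df.to_csv(Path(path), index=False, float_format="%.9g")


def read_truth(path: str | Path) -> GroundTruthEvents:
    df = pd.read_csv(Path(path))
    _require_columns(df, ["time", "foot", "kind", "pass"], Path(path).name)
    events = [
        GaitEvent(float(t), f, k, int(p))
        for t, f, k, p in zip(df["time"], df["foot"], df["kind"], df["pass"])
    ]
    step_lengths = []
    positions = []
    if "step_length" in df.columns:
        for i, v in enumerate(df["step_length"]):
            if not np.isnan(v):
                step_lengths.append((i, float(v)))
    if "position" in df.columns:
        for i, v in enumerate(df["position"]):
            if not np.isnan(v):
                positions.append((i, float(v)))
    return GroundTruthEvents(events, step_lengths, positions)


def write_events(series_list: list[EventSeries], path: str | Path) -> None:
    rows = []
    for es in series_list:
        rows += [(es.modality, es.foot, "HS", t) for t in es.hs_times]
        rows += [(es.modality, es.foot, "TO", t) for t in es.to_times]
    rows.sort(key=lambda r: r[3])
    pd.DataFrame(rows, columns=["modality", "foot", "kind", "time"]).to_csv(
        Path(path), index=False, float_format="%.9g"
    )


def read_events(path: str | Path) -> list[EventSeries]:
    df = pd.read_csv(Path(path))
    _require_columns(df, ["modality", "foot", "kind", "time"], Path(path).name)
    out = []
    for (mod, foot), grp in df.groupby(["modality", "foot"]):
        hs = np.sort(grp.loc[grp["kind"] == "HS", "time"].to_numpy())
        to = np.sort(grp.loc[grp["kind"] == "TO", "time"].to_numpy())
        out.append(EventSeries(foot=foot, hs_times=hs, to_times=to, modality=mod))
    return out


# ---------------------------------------------------------------------------
# Markers
# ---------------------------------------------------------------------------

def write_strides(strides: list[StrideRecord], path: str | Path) -> None:
    rows = []
    for s in strides:
        rows.append({
            "foot": s.foot, "start_time": s.start_time,
            "step_time": s.step_time, "stride_time": s.stride_time,
            "stance_time": s.stance_time, "swing_time": s.swing_time,
            "single_support": s.single_support, "ds_initial": s.ds_initial,
            "ds_terminal": s.ds_terminal, "ds_total": s.ds_total,
            "step_length": s.step_length, "stride_length": s.stride_length,
            "stride_velocity": s.stride_velocity,
        })
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format="%.9g")


def write_summary(summary: TrialSummary, path: str | Path) -> None:
    rows = [
        {"marker": k, "mean": summary.means[k], "sd": summary.sds.get(k, 0.0),
         "n": summary.n_strides}
        for k in summary.means
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=1, sort_keys=True))
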