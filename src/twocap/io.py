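"""Readers and writers for the pipeline's plain-text interchange formats.

Pose tables use the three-row-header CSV dialect emitted by markerless
pose trackers (scorer / bodyparts / coords rows, then one x, y, likelihood
triplet per tracked point).  Spike tables are tidy CSV (unit_id,
spike_time_s).  Schedules are one-row-per-trial CSV.  Result objects are
serialized as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BODY_PARTS,
    LANDMARKS,
    BodyPartTrack,
    BrokenStick,
    FormatError,
    ISIStats,
    PermDistanceResult,
    PoseTrack,
    SessionMetrics,
    SpikeData,
    TaskSchedule,
    Trial,
    Unit,
    ValidationError,
)

log = logging.getLogger(__name__)

_SCORER = "twocap"


# ---------------------------------------------------------------------------
# Pose tables
# ---------------------------------------------------------------------------


def write_pose_table(pose: PoseTrack, path) -> None:
    pose.validate()
    n = pose.n_frames
    cols = {}
    for part in BODY_PARTS:
        tr = pose.parts[part]
        cols[(_SCORER, part, "x")] = tr.x
        cols[(_SCORER, part, "y")] = tr.y
        cols[(_SCORER, part, "likelihood")] = tr.likelihood
    for name in LANDMARKS:
        x, y = pose.landmarks[name]
        cols[(_SCORER, name, "x")] = np.full(n, x)
        cols[(_SCORER, name, "y")] = np.full(n, y)
        cols[(_SCORER, name, "likelihood")] = np.ones(n)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["scorer", "bodyparts", "coords"])
    df.index.name = None
    df.to_csv(path, index_label="")
    # prepend fps as a comment is avoided: fps is carried by the frame rate
    # convention (30 FPS default); callers needing another rate pass it to
    # read_pose_table.


def read_pose_table(path, fps: float = 30.0) -> PoseTrack:
    """Read a three-row-header pose CSV into a :class:`PoseTrack`.

    Raises :class:`FormatError` when the header dialect is wrong and
    :class:`ValidationError` when values violate domain invariants (the
    message names the offending frame).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        head = [fh.readline() for _ in range(3)]
    labels = [line.split(",", 1)[0].strip() for line in head]
    if labels != ["scorer", "bodyparts", "coords"]:
        raise FormatError(
            f"{path}: expected three header rows scorer/bodyparts/coords, got {labels}"
        )
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    parts: dict[str, BodyPartTrack] = {}
    landmarks: dict[str, tuple[float, float]] = {}
    bodyparts = df.columns.get_level_values(1)
    for name in dict.fromkeys(bodyparts):
        sub = df.xs(name, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        if "likelihood" not in sub.columns:
            raise FormatError(f"{path}: body part {name!r} missing likelihood column")
        if name in BODY_PARTS:
            lik = sub["likelihood"].to_numpy(float)
            bad = np.flatnonzero((lik < 0) | (lik > 1))
            if bad.size:
                raise ValidationError(
                    f"{path}: {name} likelihood outside [0, 1] at frame {int(bad[0])}"
                )
            parts[name] = BodyPartTrack(
                x=sub["x"].to_numpy(float),
                y=sub["y"].to_numpy(float),
                likelihood=lik,
            )
        elif name in LANDMARKS:
            landmarks[name] = (float(sub["x"].iloc[0]), float(sub["y"].iloc[0]))
        else:
            raise ValidationError(f"{path}: unknown body-part name {name!r}")
    pose = PoseTrack(fps=fps, parts=parts, landmarks=landmarks)
    pose.validate()
    return pose


# ---------------------------------------------------------------------------
# Spike tables
# ---------------------------------------------------------------------------


def write_spike_table(spikes: SpikeData, path) -> None:
    rows = []
    for u in spikes.units:
        for t in u.spike_times:
            rows.append(
                {
                    "unit_id": u.unit_id,
                    "spike_time_s": t,
                    "isi_violation_fraction": u.isi_violation_fraction,
                    "truth_class": u.truth_class if u.truth_class is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_spike_table(path, session_id: str = "") -> SpikeData:
    """Read a tidy (unit_id, spike_time_s) CSV; spike times sorted per unit."""
    df = pd.read_csv(path)
    if "unit_id" not in df.columns or "spike_time_s" not in df.columns:
        raise FormatError(f"{path}: expected unit_id and spike_time_s columns")
    if (df["spike_time_s"] < 0).any():
        row = int(df.index[df["spike_time_s"] < 0][0])
        raise ValidationError(f"{path}: negative spike time at row {row}")
    units = []
    for uid, grp in df.groupby("unit_id", sort=True):
        times = np.sort(grp["spike_time_s"].to_numpy(float))
        viol = (
            float(grp["isi_violation_fraction"].iloc[0])
            if "isi_violation_fraction" in grp.columns
            else 0.0
        )
        truth = None
        if "truth_class" in grp.columns:
            val = grp["truth_class"].iloc[0]
            if isinstance(val, str) and val:
                truth = val
        units.append(
            Unit(
                unit_id=str(uid),
                spike_times=times,
                isi_violation_fraction=viol,
                truth_class=truth,
            )
        )
    data = SpikeData(session_id=session_id or str(path), units=units)
    data.validate()
    return data


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

_SCHED_COLS = [
    "session_id",
    "strain",
    "session_type",
    "trial_index",
    "cs_type",
    "cs_side",
    "alcohol_side",
    "cue_on",
    "cue_off",
    "sipper_in",
    "sipper_out",
    "cue_style",
]


def write_schedule(schedule: TaskSchedule, path) -> None:
    rows = []
    for t in schedule.trials:
        rows.append(
            {
                "session_id": schedule.session_id,
                "strain": schedule.strain,
                "session_type": schedule.session_type,
                "trial_index": t.index,
                "cs_type": t.cs_type,
                "cs_side": t.cs_side,
                "alcohol_side": t.alcohol_side,
                "cue_on": t.cue_on,
                "cue_off": t.cue_off,
                "sipper_in": "" if t.sipper_in is None else t.sipper_in,
                "sipper_out": "" if t.sipper_out is None else t.sipper_out,
                "cue_style": t.cue_style,
            }
        )
    pd.DataFrame(rows, columns=_SCHED_COLS).to_csv(path, index=False)


def read_schedule(path, require_full: bool = True) -> TaskSchedule:
    df = pd.read_csv(path)
    missing = [c for c in _SCHED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: schedule missing columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: empty schedule")
    trials = []
    for _, row in df.iterrows():
        sipper_in = None if pd.isna(row["sipper_in"]) else float(row["sipper_in"])
        sipper_out = None if pd.isna(row["sipper_out"]) else float(row["sipper_out"])
        trials.append(
            Trial(
                index=int(row["trial_index"]),
                cs_type=str(row["cs_type"]),
                cs_side=str(row["cs_side"]),
                alcohol_side=str(row["alcohol_side"]),
                cue_on=float(row["cue_on"]),
                cue_off=float(row["cue_off"]),
                sipper_in=sipper_in,
                sipper_out=sipper_out,
                cue_style=str(row["cue_style"]),
            )
        )
    schedule = TaskSchedule(
        session_id=str(df["session_id"].iloc[0]),
        strain=str(df["strain"].iloc[0]),
        session_type=str(df["session_type"].iloc[0]),
        trials=trials,
    )
    schedule.validate(require_full=require_full)
    return schedule


# ---------------------------------------------------------------------------
# Trial events CSV
# ---------------------------------------------------------------------------


def write_trial_events(events, path) -> None:
    """Scalar per-trial fields as CSV; CS- trials appear as cs_minus rows.

    Occupancy vectors are frame-resolution arrays and are not round-tripped
    through this table (they are recomputable from pose + schedule).
    """
    rows = []
    for i, tidx in enumerate(events.trial_index):
        rows.append(
            {
                "trial_index": int(tidx),
                "cs_type": "CS+",
                "outcome": events.outcome[i],
                "first_port_visited": events.first_port_visited[i],
                "approach_time_correct": events.approach_time_correct[i],
                "approach_time_incorrect": events.approach_time_incorrect[i],
                "latency_correct_s": events.latency_correct_s[i],
                "latency_incorrect_s": events.latency_incorrect_s[i],
            }
        )
    for i, tidx in enumerate(events.cs_minus_index):
        rows.append(
            {
                "trial_index": int(tidx),
                "cs_type": "CS-",
                "outcome": "approached" if events.cs_minus_approached[i] else "no_approach",
                "first_port_visited": "",
                "approach_time_correct": np.nan,
                "approach_time_incorrect": np.nan,
                "latency_correct_s": np.nan,
                "latency_incorrect_s": np.nan,
            }
        )
    pd.DataFrame(rows).sort_values("trial_index").to_csv(path, index=False)


def read_trial_events(path):
    """Reload the scalar fields written by :func:`write_trial_events`."""
    from .types import TrialEvents

    df = pd.read_csv(path)
    plus = df[df["cs_type"] == "CS+"]
    minus = df[df["cs_type"] == "CS-"]
    n = len(plus)
    return TrialEvents(
        trial_index=plus["trial_index"].to_numpy(int),
        outcome=list(plus["outcome"]),
        first_port_visited=[
            p if isinstance(p, str) and p else "none" for p in plus["first_port_visited"]
        ],
        approach_time_correct=plus["approach_time_correct"].to_numpy(float),
        approach_time_incorrect=plus["approach_time_incorrect"].to_numpy(float),
        latency_correct_s=plus["latency_correct_s"].to_numpy(float),
        latency_incorrect_s=plus["latency_incorrect_s"].to_numpy(float),
        occupancy_correct=np.zeros((n, 0), dtype=np.int8),
        occupancy_incorrect=np.zeros((n, 0), dtype=np.int8),
        cs_minus_index=minus["trial_index"].to_numpy(int),
        cs_minus_approached=(minus["outcome"] == "approached").to_numpy(bool),
    )


# ---------------------------------------------------------------------------
# Result JSON
# ---------------------------------------------------------------------------

_RESULT_TYPES = {
    cls.__name__: cls
    for cls in (PermDistanceResult, BrokenStick, ISIStats, SessionMetrics)
}


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        d["__type__"] = type(obj).__name__
        return d
    return obj


def write_results(obj, path) -> None:
    """Serialize a result dataclass (or plain dict) to JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1)


def read_results(path):
    """Reload JSON written by :func:`write_results`.

    Registered result dataclasses are reconstructed (array-typed fields come
    back as numpy arrays); anything else is returned as plain dict/list.
    """
    with open(path) as fh:
        data = json.load(fh)
    return _reconstruct(data)


def _reconstruct(data):
    if isinstance(data, dict) and "__type__" in data:
        cls = _RESULT_TYPES.get(data["__type__"])
        if cls is None:
            data = dict(data)
            data.pop("__type__")
            return data
        kwargs = {}
        for f in dataclasses.fields(cls):
            val = data[f.name]
            ann = str(f.type)
            if "ndarray" in ann:
                val = np.asarray(val)
            elif cls is PermDistanceResult and f.name == "subspaces":
                val = [tuple(s) for s in val]
            elif "tuple" in ann and isinstance(val, list):
                val = tuple(val)
            kwargs[f.name] = val
        return cls(**kwargs)
    if isinstance(data, dict):
        return {k: _reconstruct(v) for k, v in data.items()}
    if isinstance(data, list):
        return [_reconstruct(v) for v in data]
    return data
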