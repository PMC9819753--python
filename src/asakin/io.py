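"""Readers and writers for the text formats the pipeline consumes/produces.

Pose CSV dialect: columns ``time, r11..r33`` (row-major rotation) and
``px, py, pz``; one file per segment; header row mandatory.  Marker data is
accepted as TRC (the standard tab-separated motion-capture text format) or
as a generic wide CSV (``time, <id>_x, <id>_y, <id>_z``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .angles import AngleCurves
from .errors import InputError
from .se3 import MarkerTrajectory, PoseTrajectory
from .twists import TwistTrajectory

POSE_COLUMNS = [
    "time",
    "r11", "r12", "r13",
    "r21", "r22", "r23",
    "r31", "r32", "r33",
    "px", "py", "pz",
]


def write_pose_csv(traj: PoseTrajectory, path) -> None:
    data = np.column_stack([traj.times, traj.Rs.reshape(len(traj), 9), traj.ps])
    pd.DataFrame(data, columns=POSE_COLUMNS).to_csv(path, index=False, float_format="%.12g")


def read_pose_csv(path, frame_labels=("0", "body")) -> PoseTrajectory:
    path = Path(path)
    if not path.exists():
        raise InputError(f"pose file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"pose CSV {path} lacks columns {missing}")
    rs = df[POSE_COLUMNS[1:10]].to_numpy().reshape(-1, 3, 3)
    ps = df[["px", "py", "pz"]].to_numpy()
    return PoseTrajectory(df["time"].to_numpy(), rs, ps, tuple(frame_labels))


# ---------------------------------------------------------------------------
# Marker formats


def write_trc(traj: MarkerTrajectory, path, units: str = "m") -> None:
    """Write the cluster as a minimal standard-compliant TRC file."""
    n, m = len(traj), len(traj.marker_ids)
    rate = (n - 1) / (traj.times[-1] - traj.times[0]) if n > 1 else 100.0
    path = Path(path)
    header4 = "Frame#\tTime\t" + "\t\t\t".join(traj.marker_ids) + "\t\t\t"
    header5 = "\t\t" + "\t".join(
        f"X{k + 1}\tY{k + 1}\tZ{k + 1}" for k in range(m)
    )
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rate:.6f}\t{rate:.6f}\t{n}\t{m}\t{units}\t{rate:.6f}\t1\t{n}",
        header4,
        header5,
        "",
    ]
    for i in range(n):
        row = [str(i + 1), f"{traj.times[i]:.8f}"]
        row += [f"{v:.10f}" for v in traj.positions[i].reshape(-1)]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_trc(path, segment: str = "body") -> MarkerTrajectory:
    path = Path(path)
    if not path.exists():
        raise InputError(f"TRC file not found: {path}")
    lines = path.read_text().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise InputError(f"{path} is not a TRC file")
    meta = lines[2].split("\t")
    try:
        n_markers = int(meta[3])
        units = meta[4]
    except (IndexError, ValueError) as exc:
        raise InputError(f"malformed TRC header in {path}") from exc
    ids = [s for s in lines[3].split("\t")[2:] if s.strip()]
    if len(ids) != n_markers:
        raise InputError(
            f"TRC header announces {n_markers} markers but names {len(ids)}"
        )
    scale = 0.001 if units.lower() == "mm" else 1.0
    times, rows = [], []
    for line in lines[5:]:
        parts = line.split("\t")
        if len(parts) < 2 + 3 * n_markers or not parts[0].strip():
            continue
        times.append(float(parts[1]))
        rows.append([float(v) for v in parts[2 : 2 + 3 * n_markers]])
    pos = np.asarray(rows).reshape(len(rows), n_markers, 3) * scale
    return MarkerTrajectory(ids, pos, np.asarray(times), segment=segment)


def write_marker_csv(traj: MarkerTrajectory, path) -> None:
    cols = {"time": traj.times}
    for k, mid in enumerate(traj.marker_ids):
        for j, axis in enumerate("xyz"):
            cols[f"{mid}_{axis}"] = traj.positions[:, k, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_marker_csv(path, segment: str = "body") -> MarkerTrajectory:
    path = Path(path)
    if not path.exists():
        raise InputError(f"marker file not found: {path}")
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise InputError(f"marker CSV {path} lacks a 'time' column")
    ids = []
    for col in df.columns:
        if col.endswith("_x"):
            mid = col[:-2]
            if f"{mid}_y" in df.columns and f"{mid}_z" in df.columns:
                ids.append(mid)
    if len(ids) < 3:
        raise InputError(f"marker CSV {path} names fewer than 3 complete markers")
    pos = np.stack(
        [df[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy() for m in ids], axis=1
    )
    return MarkerTrajectory(ids, pos, df["time"].to_numpy(), segment=segment)


def read_markers(path, segment: str = "body") -> MarkerTrajectory:
    """Dispatch on extension: .trc -> TRC, anything else -> wide CSV."""
    if str(path).lower().endswith(".trc"):
        return read_trc(path, segment=segment)
    return read_marker_csv(path, segment=segment)


# ---------------------------------------------------------------------------
# Outputs


def write_twist_csv(tw: TwistTrajectory, path) -> None:
    df = pd.DataFrame(
        np.column_stack([tw.times, tw.omega, tw.v]),
        columns=["time", "wx", "wy", "wz", "vx", "vy", "vz"],
    )
    df["frame"] = tw.frame
    df.to_csv(path, index=False, float_format="%.12g")


def write_angles_csv(curves: AngleCurves, path) -> None:
    df = pd.DataFrame(
        {
            "percent_cycle": curves.percent_cycle,
            "angle1": curves.angles[:, 0],
            "angle2": curves.angles[:, 1],
            "angle3": curves.angles[:, 2],
        }
    )
    df["kind"] = curves.kind
    df["sequence"] = curves.sequence
    df["offset_removed"] = curves.offset_removed
    df.to_csv(path, index=False, float_format="%.6f")


def read_angles_csv(path) -> AngleCurves:
    df = pd.read_csv(path)
    return AngleCurves(
        df["percent_cycle"].to_numpy(),
        df[["angle1", "angle2", "angle3"]].to_numpy(),
        sequence=str(df["sequence"].iloc[0]),
        offset_removed=bool(df["offset_removed"].iloc[0]),
        kind=str(df["kind"].iloc[0]),
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
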