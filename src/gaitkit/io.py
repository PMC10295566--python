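"""Reading and writing keypoint and angle-signal files.

Keypoint files are long-format delimited text with one row per
frame x joint and columns ``frame, joint, x, y, z, visibility`` (names
remappable through a schema).  Angle files carry ``frame, joint, side,
angle_deg, visibility``.  Frame indices are 0-based; timestamps are
derived solely from the frame rate, and files with non-contiguous frame
indices are rejected rather than resampled.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .kinematics import JOINT_NAMES, AngleSignal, PoseSequence

logger = logging.getLogger(__name__)

DEFAULT_SCHEMA = {
    "frame": "frame",
    "joint": "joint",
    "x": "x",
    "y": "y",
    "z": "z",
    "visibility": "visibility",
}


class KeypointParseError(ValueError):
    """A keypoint file row could not be parsed."""


def _coerce_numeric(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 1-based
        raise KeypointParseError(
            f"{path}: malformed value {df[col][bad].iloc[0]!r} in column "
            f"{col!r} on line {line}"
        )
    return out


def read_pose_sequence(
    path: str | Path,
    fps: float = 30.0,
    schema: Mapping[str, str] | None = None,
    joint_adapter: Mapping[str, str] | None = None,
) -> PoseSequence:
    """Read a long-format keypoint file into a :class:`PoseSequence`.

    ``schema`` maps the canonical column roles to the file's column
    names; ``joint_adapter`` optionally renames estimator-specific joint
    labels into the fixed vocabulary.  Visibility values outside [0, 1]
    are clipped with a warning; a joint absent from a frame is recorded
    with visibility 0.
    """
    path = str(path)
    cols = dict(DEFAULT_SCHEMA)
    cols.update(schema or {})
    df = pd.read_csv(path)
    missing = [v for v in cols.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    if joint_adapter:
        df["joint"] = df["joint"].map(lambda j: joint_adapter.get(j, j))
    unknown = sorted(set(df["joint"]) - set(JOINT_NAMES))
    if unknown:
        raise ValueError(f"{path}: unknown joint name(s) {unknown}")
    for col in ("frame", "x", "y", "z", "visibility"):
        df[col] = _coerce_numeric(df, col, path)

    frames = np.sort(df["frame"].unique().astype(int))
    if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
        raise ValueError(f"{path}: frame indices are not contiguous")
    n = len(frames)
    coords = np.zeros((n, len(JOINT_NAMES), 3))
    visibility = np.zeros((n, len(JOINT_NAMES)))
    jidx = {name: i for i, name in enumerate(JOINT_NAMES)}
    f0 = int(frames[0])
    for row in df.itertuples(index=False):
        t = int(row.frame) - f0
        j = jidx[row.joint]
        coords[t, j] = (row.x, row.y, row.z)
        visibility[t, j] = row.visibility
    if np.any((visibility < 0) | (visibility > 1)):
        logger.warning("%s: visibility outside [0, 1] clipped", path)
        visibility = np.clip(visibility, 0.0, 1.0)
    coords[visibility == 0] = np.nan_to_num(coords[visibility == 0])
    return PoseSequence(coords=coords, visibility=visibility, fps=fps)


def write_pose_sequence(pose: PoseSequence, path: str | Path) -> None:
    """Write a pose sequence in the long-format keypoint schema."""
    rows = []
    for t in range(pose.n_frames):
        for j, name in enumerate(pose.joints):
            rows.append({
                "frame": t,
                "joint": name,
                "x": pose.coords[t, j, 0],
                "y": pose.coords[t, j, 1],
                "z": pose.coords[t, j, 2],
                "visibility": pose.visibility[t, j],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_angle_signals(path: str | Path, fps: float = 30.0) -> dict[tuple[str, str], AngleSignal]:
    """Read angle signals keyed by (side, joint) from delimited text."""
    df = pd.read_csv(path)
    needed = {"frame", "joint", "side", "angle_deg"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(needed)}")
    if "visibility" not in df.columns:
        df["visibility"] = 1.0
    out = {}
    for (side, joint), grp in df.groupby(["side", "joint"]):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise ValueError(f"{path}: non-contiguous frames for {side} {joint}")
        out[(side, joint)] = AngleSignal(
            joint=joint, side=side,
            theta=grp["angle_deg"].to_numpy(dtype=float),
            visibility=grp["visibility"].to_numpy(dtype=float),
            fps=fps,
        )
    if not out:
        raise ValueError(f"{path}: no signals found")
    return out


def write_angle_signals(
    signals: Mapping[tuple[str, str], AngleSignal], path: str | Path
) -> None:
    """Write angle signals in the schema read_angle_signals expects."""
    rows = []
    for (side, joint), sig in signals.items():
        for t in range(len(sig)):
            rows.append({
                "frame": t,
                "joint": joint,
                "side": side,
                "angle_deg": sig.theta[t],
                "visibility": sig.visibility[t],
            })
    pd.DataFrame(rows).to_csv(path, index=False)
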