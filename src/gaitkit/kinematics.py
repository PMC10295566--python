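"""Sagittal-plane joint-angle extraction from 3D pose keypoints.

The gait signals of interest are the knee and hip angles.  The knee angle
is the angle at the knee between the knee-to-hip and knee-to-ankle
vectors.  The hip angle is measured against a *virtual forward vector* —
the shoulder line rotated 90 degrees about the vertical axis — rather
than against the trunk, which avoids the fold at 180 degrees that a
trunk-referenced angle exhibits when shoulder, hip and knee align.

A pose estimator reports, per frame and joint, a 3D position and a
visibility score in [0, 1].  Angle signals inherit the *minimum*
visibility of their constituent joints: the least reliable joint governs
the reliability of the angle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig

logger = logging.getLogger(__name__)

#: Fixed joint vocabulary, in storage order.
JOINT_NAMES = (
    "left_shoulder",
    "right_shoulder",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

#: Renaming table from MediaPipe-style landmark names to our vocabulary.
BLAZEPOSE_ADAPTER = {
    "LEFT_SHOULDER": "left_shoulder",
    "RIGHT_SHOULDER": "right_shoulder",
    "LEFT_HIP": "left_hip",
    "RIGHT_HIP": "right_hip",
    "LEFT_KNEE": "left_knee",
    "RIGHT_KNEE": "right_knee",
    "LEFT_ANKLE": "left_ankle",
    "RIGHT_ANKLE": "right_ankle",
}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class DegenerateGeometryError(ValueError):
    """Raised when a joint-angle construction is geometrically undefined."""


def parse_axis(spec: str) -> np.ndarray:
    """Turn a signed axis name like ``"+y"`` into a unit 3-vector."""
    if len(spec) != 2 or spec[0] not in "+-" or spec[1] not in _AXIS_INDEX:
        raise ValueError(f"malformed axis spec {spec!r}")
    v = np.zeros(3)
    v[_AXIS_INDEX[spec[1]]] = 1.0 if spec[0] == "+" else -1.0
    return v


@dataclass
class PoseSequence:
    """Per-frame 3D keypoints and visibilities for the eight gait joints.

    ``coords`` has shape (n_frames, 8, 3) in any consistent length unit;
    ``visibility`` has shape (n_frames, 8) with values in [0, 1].  A
    joint missing from a frame is encoded as visibility 0.
    """

    coords: np.ndarray
    visibility: np.ndarray
    fps: float
    joints: tuple[str, ...] = JOINT_NAMES

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.visibility = np.asarray(self.visibility, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_joints, 3)")
        if self.visibility.shape != self.coords.shape[:2]:
            raise ValueError("visibility shape must match coords frames x joints")
        if len(self.joints) != self.coords.shape[1]:
            raise ValueError("joint name count must match coords")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.any((self.visibility < 0) | (self.visibility > 1)):
            raise ValueError("visibility must lie in [0, 1]")
        visible = self.visibility > 0
        if not np.all(np.isfinite(self.coords[visible])):
            raise ValueError("coords must be finite wherever visibility > 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def joint_index(self, name: str) -> int:
        try:
            return self.joints.index(name)
        except ValueError:
            raise KeyError(f"unknown joint {name!r}") from None

    def joint_coords(self, name: str) -> np.ndarray:
        return self.coords[:, self.joint_index(name), :]

    def joint_visibility(self, name: str) -> np.ndarray:
        return self.visibility[:, self.joint_index(name)]


@dataclass
class AngleSignal:
    """One joint's angle time series in degrees with per-frame visibility.

    ``theta`` uses NaN for frames where the angle could not be computed.
    ``side`` is ``"near"`` or ``"far"`` relative to the camera (or an
    unassigned placeholder for synthetic signals).
    """

    joint: str
    side: str
    theta: np.ndarray
    visibility: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.visibility = np.asarray(self.visibility, dtype=float)
        if self.theta.shape != self.visibility.shape or self.theta.ndim != 1:
            raise ValueError("theta and visibility must be equal-length 1-D arrays")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return len(self.theta)

    def replace(self, **kwargs) -> "AngleSignal":
        data = {
            "joint": self.joint,
            "side": self.side,
            "theta": self.theta,
            "visibility": self.visibility,
            "fps": self.fps,
        }
        data.update(kwargs)
        return AngleSignal(**data)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two 3-vectors, in [0, 180].

    The cosine argument is clamped to [-1, 1] so that nearly parallel
    vectors never produce NaN from rounding.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length vector has no direction")
    c = float(np.dot(u, v) / (nu * nv))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def knee_angle(hip: np.ndarray, knee: np.ndarray, ankle: np.ndarray) -> float:
    """Knee angle: angle at the knee between thigh and shank, degrees."""
    return angle_between(np.asarray(hip) - np.asarray(knee),
                         np.asarray(ankle) - np.asarray(knee))


def virtual_forward_vector(
    l_shoulder: np.ndarray, r_shoulder: np.ndarray, vertical_axis: np.ndarray | str
) -> np.ndarray:
    """Unit vector along the walking direction, from the shoulder line.

    Rotates the left-to-right shoulder vector by 90 degrees about the
    vertical axis (right-hand rule), which simultaneously removes any
    vertical component, then normalises.  Raises if the shoulder line is
    (anti)parallel to the vertical axis.
    """
    if isinstance(vertical_axis, str):
        vertical_axis = parse_axis(vertical_axis)
    a = np.asarray(vertical_axis, dtype=float)
    a = a / np.linalg.norm(a)
    sh = np.asarray(r_shoulder, dtype=float) - np.asarray(l_shoulder, dtype=float)
    if np.linalg.norm(sh) == 0.0:
        raise DegenerateGeometryError("coincident shoulders")
    # Rodrigues at 90 deg: rot(v) = a x v + a (a . v); the horizontal part
    # is just the cross product.
    fwd = np.cross(a, sh)
    n = np.linalg.norm(fwd)
    if n < 1e-12 * np.linalg.norm(sh):
        raise DegenerateGeometryError("shoulder line parallel to vertical axis")
    return fwd / n


def hip_angle(forward: np.ndarray, hip: np.ndarray, knee: np.ndarray) -> float:
    """Hip angle: angle between the forward vector and the thigh, degrees."""
    return angle_between(np.asarray(forward),
                         np.asarray(knee) - np.asarray(hip))


def _per_frame_angles(
    pose: PoseSequence, forward: np.ndarray, body_side: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Compute knee/hip angle and visibility series for one body side."""
    hip_c = pose.joint_coords(f"{body_side}_hip")
    knee_c = pose.joint_coords(f"{body_side}_knee")
    ankle_c = pose.joint_coords(f"{body_side}_ankle")
    vis = {
        j: pose.joint_visibility(j)
        for j in (f"{body_side}_hip", f"{body_side}_knee", f"{body_side}_ankle",
                  "left_shoulder", "right_shoulder")
    }
    n = pose.n_frames
    knee_theta = np.full(n, np.nan)
    hip_theta = np.full(n, np.nan)
    knee_vis = np.minimum.reduce(
        [vis[f"{body_side}_hip"], vis[f"{body_side}_knee"], vis[f"{body_side}_ankle"]]
    ).copy()
    hip_vis = np.minimum.reduce(
        [vis[f"{body_side}_hip"], vis[f"{body_side}_knee"],
         vis["left_shoulder"], vis["right_shoulder"]]
    ).copy()
    for t in range(n):
        try:
            knee_theta[t] = knee_angle(hip_c[t], knee_c[t], ankle_c[t])
        except DegenerateGeometryError:
            logger.warning("degenerate knee geometry on frame %d (%s side)", t, body_side)
            knee_vis[t] = 0.0
        try:
            if np.any(np.isnan(forward[t])):
                raise DegenerateGeometryError("no forward vector")
            hip_theta[t] = hip_angle(forward[t], hip_c[t], knee_c[t])
        except DegenerateGeometryError:
            logger.warning("degenerate hip geometry on frame %d (%s side)", t, body_side)
            hip_vis[t] = 0.0
    return knee_theta, knee_vis, hip_theta, hip_vis


def _forward_vectors(pose: PoseSequence, config: PipelineConfig) -> np.ndarray:
    """Per-frame virtual forward vectors, sign-disambiguated.

    The rotation handedness is the right-hand rule; if the resulting
    direction opposes the subject's net hip displacement over the clip,
    every frame's vector is flipped — the walking direction itself
    disambiguates the convention.
    """
    axis = parse_axis(config.vertical_axis)
    n = pose.n_frames
    fwd = np.full((n, 3), np.nan)
    ls = pose.joint_coords("left_shoulder")
    rs = pose.joint_coords("right_shoulder")
    for t in range(n):
        try:
            fwd[t] = virtual_forward_vector(ls[t], rs[t], axis)
        except DegenerateGeometryError:
            logger.warning("degenerate shoulder geometry on frame %d", t)
    hip_mid = 0.5 * (pose.joint_coords("left_hip") + pose.joint_coords("right_hip"))
    displacement = hip_mid[-1] - hip_mid[0]
    mean_fwd = np.nanmean(fwd, axis=0) if np.any(np.isfinite(fwd)) else np.zeros(3)
    if float(np.dot(displacement, mean_fwd)) < 0:
        fwd = -fwd
    return fwd


def assign_sides(pose: PoseSequence, config: PipelineConfig) -> dict[str, str]:
    """Map body sides (left/right) to camera sides (near/far).

    The side whose lower-limb joints (hip, knee, ankle) have the greater
    mean visibility over the clip is "near": occlusion of the far side
    manifests as reduced estimator confidence.  Exact ties fall back to
    mean position along the camera depth axis when one is configured
    (smaller depth = nearer), else left is near.
    """
    mean_vis = {}
    for body_side in ("left", "right"):
        vals = [pose.joint_visibility(f"{body_side}_{j}").mean()
                for j in ("hip", "knee", "ankle")]
        mean_vis[body_side] = float(np.mean(vals))
    if mean_vis["left"] > mean_vis["right"]:
        near = "left"
    elif mean_vis["right"] > mean_vis["left"]:
        near = "right"
    elif config.depth_axis is not None:
        axis = parse_axis(config.depth_axis)
        depth = {
            b: float(np.mean([pose.joint_coords(f"{b}_{j}") @ axis
                              for j in ("hip", "knee", "ankle")]))
            for b in ("left", "right")
        }
        near = "left" if depth["left"] <= depth["right"] else "right"
    else:
        near = "left"
    far = "right" if near == "left" else "left"
    return {near: "near", far: "far"}


def extract_angle_signals(
    pose: PoseSequence, config: PipelineConfig
) -> dict[tuple[str, str], AngleSignal]:
    """Extract the four gait signals, keyed by (camera side, joint).

    Returns a dict with keys ("near"|"far", "knee"|"hip").  Angles are
    computed on every frame with valid geometry regardless of
    visibility; gating on visibility is the Kalman filter's job.
    Degenerate frames become NaN with visibility 0.
    """
    forward = _forward_vectors(pose, config)
    side_map = assign_sides(pose, config)
    out: dict[tuple[str, str], AngleSignal] = {}
    for body_side, cam_side in side_map.items():
        k_th, k_vis, h_th, h_vis = _per_frame_angles(pose, forward, body_side)
        out[(cam_side, "knee")] = AngleSignal("knee", cam_side, k_th, k_vis, pose.fps)
        out[(cam_side, "hip")] = AngleSignal("hip", cam_side, h_th, h_vis, pose.fps)
    return out
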