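"""Synthetic fixtures: cosine gait signals, a 3D stick-walker, cohorts.

Joint-angle signals during walking are quasi-periodic and well modelled
as a sum of a few cosine harmonics of the stride frequency.  The
generators here produce

* gated angle signals — harmonic series plus Gaussian noise, with
  visibility-dropout windows during which the observed angle is
  additionally corrupted (emulating the unreliable estimates a pose
  network returns for occluded joints);
* a kinematic stick-walker whose shoulders, hips, knees and ankles are
  placed by forward kinematics from known hip/knee angle profiles, so
  the angle-extraction stage can be checked against exact ground truth;
* subject cohorts of gait feature vectors for the PCA/T2 stage.

Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .gait_params import FEATURE_ORDER, GaitFeatureVector
from .kinematics import JOINT_NAMES, AngleSignal, PoseSequence


@dataclass
class GaitSignalSpec:
    """Recipe for one quasi-periodic joint-angle signal.

    ``harmonics`` lists (multiple of the fundamental, amplitude in
    degrees, phase in radians).  ``dropout`` windows are (start frame,
    length, visibility value); inside them the observed angle is
    corrupted with extra Gaussian noise of SD ``dropout_noise_sd`` —
    low-visibility estimates are not merely flagged, they are wrong.
    """

    fundamental: float = 0.9
    harmonics: tuple[tuple[float, float, float], ...] = ((1.0, 20.0, 0.0),)
    offset: float = 90.0
    noise_sd: float = 0.0
    dropout: tuple[tuple[int, int, float], ...] = ()
    dropout_noise_sd: float = 15.0
    duration: int = 300
    fps: float = 30.0
    seed: int = 0
    joint: str = "knee"
    side: str = "near"

    def __post_init__(self) -> None:
        if self.fundamental <= 0:
            raise ValueError("fundamental must be positive")
        if self.fps <= 0 or self.duration < 2:
            raise ValueError("fps must be positive and duration >= 2")
        if self.noise_sd < 0 or self.dropout_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        for mult, amp, _ in self.harmonics:
            if amp < 0:
                raise ValueError("harmonic amplitudes must be nonnegative")
            if mult <= 0:
                raise ValueError("harmonic multiples must be positive")
        for start, length, vis in self.dropout:
            if not (0 <= start and start + length <= self.duration and length > 0):
                raise ValueError("dropout window must lie within the duration")
            if not 0 <= vis <= 1:
                raise ValueError("dropout visibility must lie in [0, 1]")


def _truth_series(spec: GaitSignalSpec) -> np.ndarray:
    t = np.arange(spec.duration)
    theta = np.full(spec.duration, float(spec.offset))
    for mult, amp, phase in spec.harmonics:
        theta += amp * np.cos(2 * np.pi * mult * spec.fundamental * t / spec.fps + phase)
    return theta


def generate_gait_signal(spec: GaitSignalSpec) -> tuple[AngleSignal, np.ndarray]:
    """Generate an observed signal and its noiseless truth.

    Returns ``(signal, truth)`` where ``signal.theta`` carries
    measurement noise (plus dropout corruption inside low-visibility
    windows) and ``truth`` is the clean harmonic series.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _truth_series(spec)
    theta = truth.copy()
    if spec.noise_sd > 0:
        theta += rng.normal(0.0, spec.noise_sd, size=spec.duration)
    visibility = np.ones(spec.duration)
    for start, length, vis in spec.dropout:
        sl = slice(start, start + length)
        visibility[sl] = vis
        if spec.dropout_noise_sd > 0:
            theta[sl] += rng.normal(0.0, spec.dropout_noise_sd, size=length)
    signal = AngleSignal(spec.joint, spec.side, theta, visibility, spec.fps)
    return signal, truth


@dataclass
class WalkerSpec:
    """Recipe for a forward-kinematic stick-walker.

    Segment lengths are in metres.  ``hip_profiles`` and
    ``knee_profiles`` map body side ("left"/"right") to the
    :class:`GaitSignalSpec` driving that joint.  The walker translates
    along ``direction`` (horizontal unit vector, vertical = +y) at
    ``speed`` m/s; ``depth_offsets`` displace each body side along the
    camera depth axis and ``base_visibility`` sets each side's baseline
    confidence (the occluded far side should get the lower value).
    """

    thigh: float = 0.45
    shank: float = 0.43
    trunk: float = 0.55
    shoulder_width: float = 0.38
    hip_profiles: Mapping[str, GaitSignalSpec] = field(default_factory=dict)
    knee_profiles: Mapping[str, GaitSignalSpec] = field(default_factory=dict)
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    speed: float = 1.2
    depth_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"left": -0.10, "right": 0.10})
    base_visibility: Mapping[str, float] = field(
        default_factory=lambda: {"left": 1.0, "right": 0.85})
    fps: float = 30.0
    duration: int = 222  # ~7.4 s; post-cut length 200 puts the 0.9 Hz
    # fundamental exactly on a DFT bin at 30 fps
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.thigh, self.shank, self.trunk, self.shoulder_width) <= 0:
            raise ValueError("segment lengths must be positive")
        if not self.hip_profiles:
            self.hip_profiles = {
                s: default_hip_profile(duration=self.duration, fps=self.fps,
                                       seed=self.seed + i)
                for i, s in enumerate(("left", "right"))
            }
        if not self.knee_profiles:
            self.knee_profiles = {
                s: default_knee_profile(duration=self.duration, fps=self.fps,
                                        seed=self.seed + 2 + i)
                for i, s in enumerate(("left", "right"))
            }
        for profs in (self.hip_profiles, self.knee_profiles):
            for s in ("left", "right"):
                if s not in profs:
                    raise ValueError(f"missing profile for side {s!r}")
                p = profs[s]
                if p.duration != self.duration or p.fps != self.fps:
                    raise ValueError("profile duration/fps must match the walker")


def default_hip_profile(duration: int = 222, fps: float = 30.0, seed: int = 0,
                        noise_sd: float = 0.0,
                        dropout: tuple = ()) -> GaitSignalSpec:
    """Physiologically plausible hip profile: ~26 deg ROM about 160 deg."""
    return GaitSignalSpec(
        fundamental=0.9,
        harmonics=((1.0, 12.0, 0.0), (2.0, 3.0, 0.7)),
        offset=160.0, noise_sd=noise_sd, dropout=dropout,
        duration=duration, fps=fps, seed=seed, joint="hip",
    )


def default_knee_profile(duration: int = 222, fps: float = 30.0, seed: int = 0,
                         noise_sd: float = 0.0,
                         dropout: tuple = ()) -> GaitSignalSpec:
    """Knee profile: ~50 deg ROM about 140 deg."""
    return GaitSignalSpec(
        fundamental=0.9,
        harmonics=((1.0, 20.0, 1.2), (2.0, 10.0, 0.0)),
        offset=140.0, noise_sd=noise_sd, dropout=dropout,
        duration=duration, fps=fps, seed=seed, joint="knee",
    )


def _observed_profile(spec: GaitSignalSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    signal, truth = generate_gait_signal(spec)
    if np.any(truth < 0) or np.any(truth > 180):
        raise ValueError("angle profile leaves [0, 180]")
    return np.clip(signal.theta, 0.0, 180.0), signal.visibility, truth


def generate_walker(spec: WalkerSpec) -> tuple[PoseSequence, dict[tuple[str, str], np.ndarray]]:
    """Emit a pose sequence from known hip/knee angle profiles.

    The hip angle is realised as the angle between the walking direction
    and the thigh, the knee angle as the angle between thigh and shank,
    so the angle-extraction stage recovers the generating profiles
    exactly at zero noise.  Returns the pose sequence and the noiseless
    truth profiles keyed by (body side, joint).
    """
    up = np.array([0.0, 1.0, 0.0])
    d = np.asarray(spec.direction, dtype=float)
    d = d - up * float(d @ up)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must have a horizontal component")
    d /= n
    depth = np.cross(d, up)  # camera depth axis; right shoulder sits at +depth

    T = spec.duration
    coords = np.zeros((T, len(JOINT_NAMES), 3))
    visibility = np.ones((T, len(JOINT_NAMES)))
    truth: dict[tuple[str, str], np.ndarray] = {}
    obs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for side in ("left", "right"):
        th, vis, tr = _observed_profile(spec.hip_profiles[side])
        obs[(side, "hip")] = (th, vis)
        truth[(side, "hip")] = tr
        th, vis, tr = _observed_profile(spec.knee_profiles[side])
        obs[(side, "knee")] = (th, vis)
        truth[(side, "knee")] = tr

    idx = {name: i for i, name in enumerate(JOINT_NAMES)}
    leg_h = spec.thigh + spec.shank
    tvec = np.arange(T) / spec.fps
    for t in range(T):
        pelvis = d * spec.speed * tvec[t] + up * leg_h
        centre_sh = pelvis + up * spec.trunk
        coords[t, idx["left_shoulder"]] = centre_sh - depth * (spec.shoulder_width / 2)
        coords[t, idx["right_shoulder"]] = centre_sh + depth * (spec.shoulder_width / 2)
        for side in ("left", "right"):
            off = depth * spec.depth_offsets[side]
            hip = pelvis + off
            phi = np.radians(obs[(side, "hip")][0][t])
            thigh_dir = np.cos(phi) * d - np.sin(phi) * up
            knee = hip + spec.thigh * thigh_dir
            psi = np.radians(obs[(side, "knee")][0][t])
            v = hip - knee  # unit * thigh; rotate by -psi in the (d, up) plane
            a, b = float(v @ d), float(v @ up)
            a2 = a * np.cos(psi) + b * np.sin(psi)
            b2 = -a * np.sin(psi) + b * np.cos(psi)
            shank_dir = (a2 * d + b2 * up) / spec.thigh
            ankle = knee + spec.shank * shank_dir
            coords[t, idx[f"{side}_hip"]] = hip
            coords[t, idx[f"{side}_knee"]] = knee
            coords[t, idx[f"{side}_ankle"]] = ankle
            base = spec.base_visibility[side]
            visibility[t, idx[f"{side}_hip"]] = min(base, obs[(side, "hip")][1][t])
            kvis = min(base, obs[(side, "knee")][1][t])
            visibility[t, idx[f"{side}_knee"]] = kvis
            visibility[t, idx[f"{side}_ankle"]] = kvis
    pose = PoseSequence(coords=coords, visibility=visibility, fps=spec.fps)
    return pose, truth


#: Default per-feature (mean, sd, low, high) for synthetic cohorts,
#: loosely emulating a young-adult normal cohort.
DEFAULT_FEATURE_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "age": (21.0, 3.0, 17.0, 32.0),
    "mass": (68.0, 10.0, 45.0, 100.0),
    "height": (1.72, 0.09, 1.50, 2.00),
    "flexion_far_knee": (60.0, 8.0, 20.0, 120.0),
    "flexion_far_hip": (30.0, 5.0, 10.0, 70.0),
    "flexion_near_knee": (60.0, 8.0, 20.0, 120.0),
    "flexion_near_hip": (30.0, 5.0, 10.0, 70.0),
    "striding_speed": (0.9, 0.1, 0.4, 1.6),
}


def generate_cohort(
    n: int,
    stratum: str,
    distributions: Mapping[str, tuple[float, float, float, float]] | None = None,
    seed: int = 0,
) -> list[GaitFeatureVector]:
    """Draw n feature vectors with truncated-Gaussian features."""
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = dict(DEFAULT_FEATURE_DISTRIBUTIONS)
    if distributions:
        dists.update(distributions)
    for name in FEATURE_ORDER:
        mean, sd, low, high = dists[name]
        if sd < 0 or low > high:
            raise ValueError(f"invalid distribution for {name!r}")
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n):
        values = {}
        for name in FEATURE_ORDER:
            mean, sd, low, high = dists[name]
            values[name] = float(np.clip(rng.normal(mean, sd), low, high))
        cohort.append(GaitFeatureVector(gender=stratum, **values))
    return cohort
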