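"""Discrete gait parameters decoded from filtered angle signals.

Two summaries feed the feature model: joint *flexion*, implemented as
the range of motion (max minus min) of the filtered signal in degrees,
and *striding speed*, the dominant frequency of the near-side hip signal
in strides per second.  Together with age, mass and height they form an
8-dimensional feature vector per subject; gender is carried alongside as
a stratification key, not a feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .config import PipelineConfig
from .freq_filter import dominant_frequency, lrmse_select
from .kinematics import AngleSignal

logger = logging.getLogger(__name__)

#: Fixed, versioned feature order; stored feature models depend on it.
FEATURE_ORDER = (
    "age",
    "mass",
    "height",
    "flexion_far_knee",
    "flexion_far_hip",
    "flexion_near_knee",
    "flexion_near_hip",
    "striding_speed",
)

FEATURE_ORDER_VERSION = 1


@dataclass
class GaitFeatureVector:
    """One subject's discrete gait features (one PCA input row).

    Units: age in years, mass in kg, height in m, flexions in degrees,
    striding speed in strides/s.  ``gender`` is a stratum label only.
    """

    age: float
    mass: float
    height: float
    flexion_far_knee: float
    flexion_far_hip: float
    flexion_near_knee: float
    flexion_near_hip: float
    striding_speed: float
    gender: str

    def __post_init__(self) -> None:
        for name in FEATURE_ORDER:
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"feature {name!r} must be a finite number")
        for name in FEATURE_ORDER[3:7]:
            if getattr(self, name) < 0:
                raise ValueError(f"flexion {name!r} must be nonnegative")
        if self.striding_speed <= 0:
            raise ValueError("striding_speed must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_ORDER], dtype=float)


def flexion(signal: AngleSignal) -> float:
    """Range of motion of a filtered signal: max(theta) - min(theta), degrees."""
    if len(signal) == 0:
        raise ValueError("empty signal")
    if not np.all(np.isfinite(signal.theta)):
        raise ValueError("signal has missing samples; filter before summarising")
    rom = float(np.max(signal.theta) - np.min(signal.theta))
    if rom == 0.0:
        logger.warning("constant %s %s signal: flexion is 0", signal.side, signal.joint)
    return rom


def striding_speed(near_hip: AngleSignal, config: PipelineConfig) -> float:
    """Strides per second from the near-side hip signal.

    The stride rate is read off as the dominant frequency of the
    signal's least-RMSE spectral selection: one hip flexion-extension
    cycle per stride.
    """
    selection = lrmse_select(near_hip.theta, config.n_components, fs=near_hip.fps)
    return dominant_frequency(selection)


def assemble_features(
    subject: Mapping[str, object],
    signals: Mapping[tuple[str, str], AngleSignal],
    config: PipelineConfig,
) -> GaitFeatureVector:
    """Build a subject's feature vector from metadata and filtered signals.

    ``subject`` must provide age, mass, height and gender; ``signals``
    must hold the four filtered signals keyed by (side, joint).
    """
    for key in ("age", "mass", "height", "gender"):
        if key not in subject or subject[key] is None:
            raise ValueError(f"subject metadata missing {key!r}")
    for key in (("far", "knee"), ("far", "hip"), ("near", "knee"), ("near", "hip")):
        if key not in signals:
            raise ValueError(f"missing filtered signal for {key}")
    return GaitFeatureVector(
        age=float(subject["age"]),  # type: ignore[arg-type]
        mass=float(subject["mass"]),  # type: ignore[arg-type]
        height=float(subject["height"]),  # type: ignore[arg-type]
        flexion_far_knee=flexion(signals[("far", "knee")]),
        flexion_far_hip=flexion(signals[("far", "hip")]),
        flexion_near_knee=flexion(signals[("near", "knee")]),
        flexion_near_hip=flexion(signals[("near", "hip")]),
        striding_speed=striding_speed(signals[("near", "hip")], config),
        gender=str(subject["gender"]),
    )
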