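"""End-to-end orchestration: keypoints to gait report.

The pipeline runs angle extraction, side-specific Kalman filtering,
frequency-domain denoising, discrete-parameter decoding and — when a
cohort feature model is supplied — Hotelling T2 scoring, and bundles
the results with provenance into a JSON-serialisable report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from . import feature_model as fm
from . import freq_filter, gait_params, kalman, kinematics
from .config import PipelineConfig

#: Clips shorter than this hold too little of a walking period to assess.
MIN_FRAMES = 40


@dataclass
class GaitReport:
    """Structured output of one pipeline run."""

    signals: dict[str, list[float]]
    flexions: dict[str, float]
    striding_speed: float
    t2: Optional[float]
    provenance: dict[str, object]

    def to_dict(self) -> dict:
        return {
            "signals": self.signals,
            "flexions": self.flexions,
            "striding_speed": self.striding_speed,
            "t2": self.t2,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def filter_signals(
    raw: Mapping[tuple[str, str], kinematics.AngleSignal], config: PipelineConfig
) -> dict[tuple[str, str], kinematics.AngleSignal]:
    """Kalman-filter then FDF-denoise each of the four raw signals."""
    out = {}
    for (side, joint), signal in raw.items():
        kcfg = kalman.select_side_config(side, config)
        filtered, _ = kalman.kf_filter_signal(signal, kcfg)
        out[(side, joint)] = freq_filter.fdf_filter(filtered, config)
    return out


def run_pipeline(
    pose: kinematics.PoseSequence,
    subject: Mapping[str, object],
    config: PipelineConfig,
    model: Optional[fm.FeatureModel] = None,
    input_id: str = "",
) -> GaitReport:
    """Run the full assessment pipeline on one pose sequence.

    Requires at least 40 frames (a minimal walking period) and at least
    one partly visible frame per joint.  The report carries the four
    filtered signals, the four flexions, the striding speed, and a T2
    score iff ``model`` was given.
    """
    if pose.n_frames < MIN_FRAMES:
        raise ValueError(
            f"sequence has {pose.n_frames} frames; at least {MIN_FRAMES} "
            "are needed for a walking period"
        )
    for name in pose.joints:
        if np.all(pose.joint_visibility(name) == 0):
            raise ValueError(f"joint {name!r} is never visible")

    raw = kinematics.extract_angle_signals(pose, config)
    filtered = filter_signals(raw, config)

    flexions = {f"{side}_{joint}": gait_params.flexion(sig)
                for (side, joint), sig in filtered.items()}
    speed = gait_params.striding_speed(filtered[("near", "hip")], config)

    t2: Optional[float] = None
    if model is not None:
        features = gait_params.assemble_features(subject, filtered, config)
        t2 = fm.t2_score(model, features, config.t2_normalisation)

    lengths = {len(sig) for sig in filtered.values()}
    assert len(lengths) == 1, "filtered signals must share a length"
    return GaitReport(
        signals={f"{side}_{joint}": sig.theta.tolist()
                 for (side, joint), sig in filtered.items()},
        flexions=flexions,
        striding_speed=speed,
        t2=t2,
        provenance={
            "config_hash": config.config_hash(),
            "input_id": input_id,
            "n_frames": pose.n_frames,
            "fps": pose.fps,
        },
    )
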