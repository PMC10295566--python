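"""Pipeline configuration.

All tunable knobs of the assessment pipeline live in a single validated
:class:`PipelineConfig`.  The defaults are the operating point of the
system: a 40 % visibility threshold below which a pose-estimator joint is
treated as lost, a 10 % burn-in prefix dropped before the frequency-domain
filter, five retained spectral components, and two Kalman noise pairs —
one for the camera-facing (near) body side and one for the occluded (far)
side.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any, Literal, Optional

from pydantic import BaseModel, Field, field_validator

#: Signed coordinate axes accepted for ``vertical_axis`` / ``depth_axis``.
AXIS_NAMES = ("+x", "-x", "+y", "-y", "+z", "-z")


class PipelineConfig(BaseModel):
    """Validated configuration for the end-to-end gait pipeline.

    Parameters
    ----------
    fps:
        Video frame rate in frames per second.  Frame timestamps are
        derived solely from this value; irregular sampling is rejected
        upstream rather than resampled.
    visibility_threshold:
        Fraction in [0, 1].  Frames whose signal visibility falls below
        this are treated as missing measurements by the Kalman filter.
    cut:
        Fraction in [0, 1) of leading frames discarded before the
        frequency-domain filter, allowing the Kalman recursion to
        converge first.
    n_components:
        Number of DFT components (DC and each conjugate pair counting as
        one) retained by the least-RMSE spectral selection.
    alpha_far, beta_far, alpha_near, beta_near:
        Process-noise (alpha) and measurement-noise (beta) coefficients
        for the far- and near-side Kalman filters.
    variance_threshold:
        Cumulative explained-variance fraction that the PCA feature
        model must reach.
    vertical_axis:
        Signed world axis pointing up, e.g. ``"+y"``; used to build the
        virtual forward vector for the hip angle.
    depth_axis:
        Optional signed axis pointing from the camera into the scene;
        used only as a tie-break when assigning near/far sides.
    kf_mode:
        Missing-measurement substitution strategy: ``"KF1"`` feeds the
        prior estimate back as the measurement, ``"KF2"`` the previous
        posterior.
    p0_scale:
        Diagonal value of the initial error covariance.
    t2_normalisation:
        ``"none"`` reports the raw Hotelling statistic; ``"per_pc"``
        divides it by the number of retained components.
    pose_estimator_passthrough:
        Free-form options recorded for provenance and handed verbatim to
        an external pose estimator (e.g. segmentation-mask or detection
        confidence settings); never interpreted here.
    """

    fps: float = Field(default=30.0, gt=0)
    visibility_threshold: float = Field(default=0.40, ge=0, le=1)
    cut: float = Field(default=0.10, ge=0, lt=1)
    n_components: int = Field(default=5, ge=1)
    alpha_far: float = Field(default=1e-2, gt=0)
    beta_far: float = Field(default=1e-3, gt=0)
    alpha_near: float = Field(default=10.0, gt=0)
    beta_near: float = Field(default=1.0, gt=0)
    variance_threshold: float = Field(default=0.90, gt=0, le=1)
    vertical_axis: str = Field(default="+y")
    depth_axis: Optional[str] = Field(default=None)
    kf_mode: Literal["KF1", "KF2"] = "KF2"
    p0_scale: float = Field(default=100.0, gt=0)
    t2_normalisation: Literal["none", "per_pc"] = "none"
    pose_estimator_passthrough: dict[str, Any] = Field(default_factory=dict)

    @field_validator("vertical_axis", "depth_axis")
    @classmethod
    def _check_axis(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in AXIS_NAMES:
            raise ValueError(f"axis must be one of {AXIS_NAMES}, got {v!r}")
        return v

    def config_hash(self) -> str:
        """Stable hex digest of the configuration, for report provenance."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
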