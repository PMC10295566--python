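"""Constant-acceleration Kalman filtering of joint-angle signals.

The state is (angle, angular velocity, angular acceleration); the single
measurement is the angle observed by the pose estimator.  Frames whose
visibility falls below the threshold are treated as missing and the
measurement is substituted:

* **KF1** feeds back the one-step prior estimate, so the filter free-runs
  on the linear kinematic model during a dropout and can diverge on
  non-linear (curved) stretches of the gait cycle;
* **KF2** feeds back the previous *posterior* estimate, which tethers the
  filter to its last corrected value and tracks curved signals through
  dropouts far better.

The process-noise covariance is ``alpha * I`` and the measurement noise
is the scalar ``beta`` — the measurement being a single angle, the
innovation is 1x1.  Near- and far-side signals get separate (alpha,
beta) pairs because the occluded far side is substantially noisier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .kinematics import AngleSignal


@dataclass
class KalmanConfig:
    """Noise and gating parameters for one filter pass.

    ``alpha``: process-noise coefficient (Q = alpha * I3);
    ``beta``: measurement-noise variance (scalar R);
    ``dt``: inter-frame interval in seconds;
    ``p0_scale``: diagonal of the initial error covariance;
    ``mode``: missing-measurement strategy, "KF1" or "KF2";
    ``visibility_threshold``: fraction below which a frame is missing.
    """

    alpha: float
    beta: float
    dt: float
    p0_scale: float = 100.0
    mode: str = "KF2"
    visibility_threshold: float = 0.40

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.dt, self.p0_scale) <= 0:
            raise ValueError("alpha, beta, dt and p0_scale must be positive")
        if self.mode not in ("KF1", "KF2"):
            raise ValueError(f"mode must be 'KF1' or 'KF2', got {self.mode!r}")


@dataclass
class KalmanState:
    """Filter state: posterior (s, P) and, after predict, prior (s, P)."""

    s: np.ndarray
    P: np.ndarray
    prior_s: np.ndarray | None = None
    prior_P: np.ndarray | None = None

    @property
    def posterior_theta(self) -> float:
        return float(self.s[0])

    @property
    def prior_theta(self) -> float:
        if self.prior_s is None:
            raise ValueError("predict has not been applied")
        return float(self.prior_s[0])


def transition_matrix(dt: float) -> np.ndarray:
    """Constant-acceleration state transition over one frame."""
    return np.array([[1.0, dt, 0.5 * dt * dt],
                     [0.0, 1.0, dt],
                     [0.0, 0.0, 1.0]])


#: Measurement matrix: the observed quantity is the angle itself.
H = np.array([[1.0, 0.0, 0.0]])


def initial_state(theta0: float, config: KalmanConfig) -> KalmanState:
    """Seed the filter at an observed angle with zero velocity/acceleration."""
    return KalmanState(s=np.array([theta0, 0.0, 0.0]),
                       P=config.p0_scale * np.eye(3))


def kf_predict(state: KalmanState, config: KalmanConfig) -> KalmanState:
    """One-step prediction: prior_s = A s, prior_P = A P A' + alpha*I."""
    A = transition_matrix(config.dt)
    prior_s = A @ state.s
    prior_P = A @ state.P @ A.T + config.alpha * np.eye(3)
    return KalmanState(s=state.s, P=state.P, prior_s=prior_s, prior_P=prior_P)


def kf_update(state: KalmanState, z: float, config: KalmanConfig) -> KalmanState:
    """Scalar-measurement update of a predicted state.

    K = P- H' / (H P- H' + beta); s = s- + K (z - H s-); P = (I - K H) P-.
    The posterior covariance is re-symmetrised to suppress round-off
    drift over long runs.
    """
    if state.prior_s is None or state.prior_P is None:
        raise ValueError("kf_update requires a predicted state (call kf_predict)")
    if not np.isfinite(z):
        raise ValueError("measurement must be finite")
    innovation_var = (H @ state.prior_P @ H.T).item() + config.beta
    K = (state.prior_P @ H.T) / innovation_var  # (3, 1)
    s = state.prior_s + (K[:, 0] * (z - (H @ state.prior_s).item()))
    P = (np.eye(3) - K @ H) @ state.prior_P
    P = 0.5 * (P + P.T)
    return KalmanState(s=s, P=P, prior_s=state.prior_s, prior_P=state.prior_P)


@dataclass
class FilterTrace:
    """Per-frame record of the filter run.

    ``z`` is the measurement actually fed to the update on each frame —
    observed angle or substituted estimate — so the substitution
    strategy is directly assertable.  ``measured`` flags frames where a
    real observation was used.  Frames before initialisation hold NaN.
    """

    z: np.ndarray
    prior_theta: np.ndarray
    posterior_theta: np.ndarray
    measured: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "z": self.z,
            "prior_theta": self.prior_theta,
            "posterior_theta": self.posterior_theta,
            "measured": self.measured,
        })


def kf_filter_signal(
    signal: AngleSignal, config: KalmanConfig
) -> tuple[AngleSignal, FilterTrace]:
    """Filter a gated angle signal, imputing low-visibility frames.

    A frame is a valid measurement when its visibility reaches the
    threshold and its angle is finite.  The filter initialises at the
    first valid frame (angle seed, zero velocity and acceleration);
    earlier frames are back-filled with the seed value.  Missing frames
    substitute the prior (KF1) or previous posterior (KF2) estimate for
    the measurement.  Returns the posterior angle sequence and the full
    trace.
    """
    n = len(signal)
    if n == 0:
        raise ValueError("empty signal")
    valid = (signal.visibility >= config.visibility_threshold) & np.isfinite(signal.theta)
    if not np.any(valid):
        raise ValueError(
            f"no frame of the {signal.side} {signal.joint} signal reaches "
            f"visibility {config.visibility_threshold}; filter cannot initialise"
        )
    first = int(np.argmax(valid))
    theta_out = np.empty(n)
    z_log = np.full(n, np.nan)
    prior_log = np.full(n, np.nan)
    post_log = np.full(n, np.nan)
    measured = np.zeros(n, dtype=bool)

    state = initial_state(float(signal.theta[first]), config)
    theta_out[: first + 1] = state.posterior_theta
    z_log[first] = signal.theta[first]
    post_log[first] = state.posterior_theta
    measured[first] = True

    for t in range(first + 1, n):
        state = kf_predict(state, config)
        prior_log[t] = state.prior_theta
        if valid[t]:
            z = float(signal.theta[t])
            measured[t] = True
        elif config.mode == "KF1":
            z = state.prior_theta
        else:  # KF2
            z = float(post_log[t - 1]) if np.isfinite(post_log[t - 1]) else state.posterior_theta
        state = kf_update(state, z, config)
        z_log[t] = z
        post_log[t] = state.posterior_theta
        theta_out[t] = state.posterior_theta

    filtered = signal.replace(theta=theta_out, visibility=signal.visibility.copy())
    trace = FilterTrace(z=z_log, prior_theta=prior_log,
                        posterior_theta=post_log, measured=measured)
    return filtered, trace


def select_side_config(side: str, config: PipelineConfig) -> KalmanConfig:
    """Kalman noise pair for a camera side, from the pipeline config."""
    if side == "far":
        alpha, beta = config.alpha_far, config.beta_far
    elif side == "near":
        alpha, beta = config.alpha_near, config.beta_near
    else:
        raise ValueError(f"side must be 'near' or 'far', got {side!r}")
    return KalmanConfig(
        alpha=alpha,
        beta=beta,
        dt=1.0 / config.fps,
        p0_scale=config.p0_scale,
        mode=config.kf_mode,
        visibility_threshold=config.visibility_threshold,
    )


def noise_grid_search(
    pairs: list[tuple[AngleSignal, AngleSignal]],
    alphas: list[float],
    betas: list[float],
    config: PipelineConfig,
):
    """Evaluate (alpha, beta) combinations against gold-standard signals.

    For each grid cell, every (observed, gold) pair is Kalman-filtered
    with that noise pair, denoised with the frequency-domain filter, and
    compared against the identically-trimmed gold signal.  Returns a
    DataFrame with columns alpha, beta, dtw (summed normalised DTW
    distance) and pe (summed percentage error).
    """
    import pandas as pd

    from . import freq_filter, metrics

    if not pairs:
        raise ValueError("no signal pairs supplied")
    if not alphas or not betas:
        raise ValueError("empty parameter grid")
    rows = []
    for alpha in alphas:
        for beta in betas:
            total_dtw = 0.0
            total_pe = 0.0
            for observed, gold in pairs:
                kcfg = KalmanConfig(
                    alpha=alpha, beta=beta, dt=1.0 / config.fps,
                    p0_scale=config.p0_scale, mode=config.kf_mode,
                    visibility_threshold=config.visibility_threshold,
                )
                filtered, _ = kf_filter_signal(observed, kcfg)
                denoised = freq_filter.fdf_filter(filtered, config)
                gold_cut = freq_filter.apply_cut(gold, config.cut)
                total_dtw += metrics.dtw_distance(
                    gold_cut.theta, denoised.theta, normalise=True
                )
                total_pe += metrics.percentage_error(
                    [[denoised.theta]], [[gold_cut.theta]]
                )
            rows.append({"alpha": alpha, "beta": beta,
                         "dtw": total_dtw, "pe": total_pe})
    return pd.DataFrame(rows)
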