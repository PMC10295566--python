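"""Kalman filter: prediction/update algebra, missing-measurement
substitution strategies, covariance health, and the KF2-over-KF1
advantage on quasi-periodic signals with dropout."""

import numpy as np
import pytest

from conftest import make_signal
from gaitkit import PipelineConfig
from gaitkit.kalman import (KalmanConfig, KalmanState, initial_state,
                            kf_filter_signal, kf_predict, kf_update,
                            noise_grid_search, select_side_config,
                            transition_matrix)
from gaitkit.synthetic import GaitSignalSpec, generate_gait_signal


def textbook_kf_step(s, P, z, A, Q, beta):
    """Independent scalar-measurement Kalman step, straight from the
    standard equations, for cross-checking."""
    H = np.array([[1.0, 0.0, 0.0]])
    s_prior = A @ s
    P_prior = A @ P @ A.T + Q
    S = P_prior[0, 0] + beta
    K = P_prior @ H.T / S
    s_post = s_prior + (K * (z - s_prior[0]))[:, 0]
    P_post = (np.eye(3) - K @ H) @ P_prior
    return s_prior, P_prior, s_post, P_post


@pytest.fixture
def cfg():
    return KalmanConfig(alpha=10.0, beta=1.0, dt=1 / 30)


def test_predict_zero_motion_state(cfg):
    st = kf_predict(initial_state(10.0, cfg), cfg)
    assert st.prior_theta == pytest.approx(10.0)


def test_predict_advances_by_velocity():
    cfg = KalmanConfig(alpha=1.0, beta=1.0, dt=1 / 30)
    st = KalmanState(s=np.array([0.0, 30.0, 0.0]), P=np.eye(3))
    assert kf_predict(st, cfg).prior_theta == pytest.approx(1.0)


def test_predict_matches_matrix_arithmetic(cfg):
    rng = np.random.default_rng(11)
    for _ in range(50):
        s = rng.normal(size=3)
        M = rng.normal(size=(3, 3))
        P = M @ M.T
        st = kf_predict(KalmanState(s=s, P=P), cfg)
        A = transition_matrix(cfg.dt)
        np.testing.assert_allclose(st.prior_s, A @ s, atol=1e-12)
        np.testing.assert_allclose(st.prior_P, A @ P @ A.T + cfg.alpha * np.eye(3),
                                   atol=1e-12)


def test_update_exact_measurement_limit():
    cfg = KalmanConfig(alpha=1.0, beta=1e-12, dt=1 / 30)
    st = kf_update(kf_predict(initial_state(0.0, cfg), cfg), 42.0, cfg)
    assert st.posterior_theta == pytest.approx(42.0, abs=1e-6)


def test_update_ignored_measurement_limit():
    cfg = KalmanConfig(alpha=1e-6, beta=1e12, dt=1 / 30)
    predicted = kf_predict(initial_state(10.0, cfg), cfg)
    st = kf_update(predicted, 99.0, cfg)
    assert st.posterior_theta == pytest.approx(predicted.prior_theta, abs=1e-6)


def test_update_matches_textbook_oracle(cfg):
    rng = np.random.default_rng(23)
    for _ in range(50):
        s = rng.normal(size=3) * 10
        M = rng.normal(size=(3, 3))
        P = M @ M.T + 0.1 * np.eye(3)
        z = rng.normal() * 20
        st = kf_update(kf_predict(KalmanState(s=s, P=P), cfg), z, cfg)
        A = transition_matrix(cfg.dt)
        _, _, s_ref, P_ref = textbook_kf_step(s, P, z, A, cfg.alpha * np.eye(3),
                                              cfg.beta)
        np.testing.assert_allclose(st.s, s_ref, atol=1e-10)
        np.testing.assert_allclose(st.P, P_ref, atol=1e-10)


def test_update_requires_prediction_and_finite_z(cfg):
    with pytest.raises(ValueError):
        kf_update(initial_state(0.0, cfg), 1.0, cfg)
    with pytest.raises(ValueError):
        kf_update(kf_predict(initial_state(0.0, cfg), cfg), np.nan, cfg)


def test_constant_signal_converges(cfg):
    sig = make_signal(np.full(100, 90.0))
    out, _ = kf_filter_signal(sig, cfg)
    assert np.all(np.abs(out.theta[20:] - 90.0) < 0.01)


def test_kf2_substitution_is_previous_posterior():
    cfg = KalmanConfig(alpha=10.0, beta=1.0, dt=1 / 30, mode="KF2")
    vis = np.ones(60)
    vis[30:35] = 0.1
    sig = make_signal(90 + 10 * np.cos(np.arange(60) / 5), vis)
    _, trace = kf_filter_signal(sig, cfg)
    for t in range(30, 35):
        assert not trace.measured[t]
        assert trace.z[t] == pytest.approx(trace.posterior_theta[t - 1], abs=1e-12)


def test_kf1_substitution_is_prior():
    cfg = KalmanConfig(alpha=10.0, beta=1.0, dt=1 / 30, mode="KF1")
    vis = np.ones(60)
    vis[30:35] = 0.1
    sig = make_signal(90 + 10 * np.cos(np.arange(60) / 5), vis)
    _, trace = kf_filter_signal(sig, cfg)
    for t in range(30, 35):
        assert trace.z[t] == pytest.approx(trace.prior_theta[t], abs=1e-12)


def test_kf1_kf2_identical_without_dropout():
    sig, _ = generate_gait_signal(GaitSignalSpec(noise_sd=2.0, seed=5))
    outs = {}
    for mode in ("KF1", "KF2"):
        cfg = KalmanConfig(alpha=10.0, beta=1.0, dt=1 / 30, mode=mode)
        outs[mode], _ = kf_filter_signal(sig, cfg)
    np.testing.assert_array_equal(outs["KF1"].theta, outs["KF2"].theta)


def test_uninitialisable_signal_raises(cfg):
    sig = make_signal(np.full(50, 90.0), np.full(50, 0.1))
    with pytest.raises(ValueError, match="cannot initialise"):
        kf_filter_signal(sig, cfg)


def test_identity_in_small_beta_limit():
    """With every frame visible and vanishing measurement noise the
    filter passes the signal through."""
    cfg = KalmanConfig(alpha=1.0, beta=1e-12, dt=1 / 30)
    sig, _ = generate_gait_signal(GaitSignalSpec(noise_sd=1.0, seed=2, duration=100))
    out, _ = kf_filter_signal(sig, cfg)
    np.testing.assert_allclose(out.theta, sig.theta, atol=1e-5)


def test_covariance_stays_symmetric_psd_long_run():
    cfg = KalmanConfig(alpha=0.01, beta=0.001, dt=1 / 30)
    rng = np.random.default_rng(4)
    state = initial_state(90.0, cfg)
    for t in range(10_000):
        state = kf_update(kf_predict(state, cfg), 90 + rng.normal(), cfg)
        if t % 500 == 0:
            np.testing.assert_allclose(state.P, state.P.T, atol=1e-12)
    eig = np.linalg.eigvalsh(state.P)
    assert np.all(eig >= -1e-9)


def test_kf2_beats_kf1_on_dropout_monte_carlo():
    """Mean RMSE over the dropout window, 100 seeded dropout placements
    on a two-harmonic gait signal: posterior substitution (KF2) tracks
    curvature that prior substitution (KF1) extrapolates away from."""
    rmse = {"KF1": [], "KF2": []}
    for seed in range(100):
        rng = np.random.default_rng(seed)
        start = int(rng.integers(40, 240))
        spec = GaitSignalSpec(noise_sd=1.0, seed=seed,
                              harmonics=((1.0, 20.0, 0.0), (2.0, 8.0, 0.5)),
                              dropout=((start, 15, 0.2),))
        sig, truth = generate_gait_signal(spec)
        for mode in ("KF1", "KF2"):
            cfg = KalmanConfig(alpha=10.0, beta=1.0, dt=1 / 30, mode=mode)
            out, _ = kf_filter_signal(sig, cfg)
            w = slice(start, start + 15)
            rmse[mode].append(np.sqrt(np.mean((out.theta[w] - truth[w]) ** 2)))
    assert np.mean(rmse["KF2"]) <= np.mean(rmse["KF1"])


def test_select_side_config_defaults():
    config = PipelineConfig()
    far = select_side_config("far", config)
    assert (far.alpha, far.beta) == (1e-2, 1e-3)
    near = select_side_config("near", config)
    assert (near.alpha, near.beta) == (10.0, 1.0)
    custom = PipelineConfig(alpha_far=0.5, beta_far=0.25)
    assert select_side_config("far", custom).alpha == 0.5
    with pytest.raises(ValueError):
        select_side_config("left", config)


def test_noise_grid_search_structure():
    config = PipelineConfig()
    spec = GaitSignalSpec(noise_sd=2.0, seed=9, duration=120)
    sig, truth = generate_gait_signal(spec)
    gold = make_signal(truth)
    table = noise_grid_search([(sig, gold)], [0.1, 10.0], [0.01, 1.0], config)
    assert len(table) == 4
    assert set(table.columns) == {"alpha", "beta", "dtw", "pe"}
    # each cell reproducible independently
    from gaitkit import freq_filter, metrics
    from gaitkit.kalman import KalmanConfig, kf_filter_signal
    row = table.iloc[2]
    kcfg = KalmanConfig(alpha=row["alpha"], beta=row["beta"], dt=1 / config.fps)
    filt, _ = kf_filter_signal(sig, kcfg)
    den = freq_filter.fdf_filter(filt, config)
    gcut = freq_filter.apply_cut(gold, config.cut)
    assert row["dtw"] == pytest.approx(
        metrics.dtw_distance(gcut.theta, den.theta, normalise=True))
    with pytest.raises(ValueError):
        noise_grid_search([], [1.0], [1.0], config)


def test_noiseless_signal_gives_near_zero_pe():
    config = PipelineConfig()
    # band-limited noiseless signal, bin-aligned after the cut
    spec = GaitSignalSpec(noise_sd=0.0, seed=0, duration=111, fundamental=0.9,
                          harmonics=((1.0, 15.0, 0.3), (2.0, 5.0, 0.0)))
    sig, truth = generate_gait_signal(spec)
    gold = make_signal(truth)
    table = noise_grid_search([(sig, gold)], [10.0], [0.001], config)
    assert float(table["pe"].iloc[0]) < 2.0
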