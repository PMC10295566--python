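"""Agreement metrics: missing-data substitution, percentage error
against a single-loop formula oracle, DTW against brute-force path
enumeration, Bland-Altman and correlation/regression closed forms."""



import numpy as np
import pytest
from scipy import stats

from conftest import make_signal
from gaitkit.metrics import (aggregate_joint_metrics, bland_altman,
                             correlation_regression, dtw_distance,
                             fill_missing, percentage_error,
                             relative_improvement)


# ---------------------------------------------------------------- fill

def test_fill_mean():
    out = fill_missing(make_signal([1.0, np.nan, 3.0]), "mean")
    np.testing.assert_array_equal(out.theta, [1.0, 2.0, 3.0])


def test_fill_locf():
    out = fill_missing(make_signal([1.0, np.nan, 3.0]), "locf")
    np.testing.assert_array_equal(out.theta, [1.0, 1.0, 3.0])


def test_fill_locf_leading_backfill():
    out = fill_missing(make_signal([np.nan, 2.0]), "locf")
    np.testing.assert_array_equal(out.theta, [2.0, 2.0])


def test_fill_all_missing_raises():
    with pytest.raises(ValueError):
        fill_missing(make_signal([np.nan, np.nan]), "mean")


# ------------------------------------------------------------------ PE

def pe_oracle(pred, gold):
    """Direct single-loop evaluation of the nested-average formula."""
    total = 0.0
    for ps, gs in zip(pred, gold):
        joint_sum = 0.0
        for p, g in zip(ps, gs):
            rmse = np.sqrt(np.mean((np.asarray(p) - np.asarray(g)) ** 2))
            joint_sum += rmse / (np.max(g) - np.min(g))
        total += joint_sum / len(ps)
    return 100.0 * total / len(pred)


def test_pe_zero_for_identical():
    g = [[np.sin(np.arange(50.0))]]
    assert percentage_error(g, g) == 0.0


def test_pe_constant_offset_closed_form():
    g = np.array([0.0, 10.0, 5.0, 2.0])  # range 10
    p = g + 3.0
    assert percentage_error([[p]], [[g]]) == pytest.approx(30.0)


def test_pe_matches_formula_oracle():
    rng = np.random.default_rng(17)
    pred = [[rng.normal(size=40) * 20 for _ in range(2)] for _ in range(3)]
    gold = [[rng.normal(size=40) * 20 for _ in range(2)] for _ in range(3)]
    assert percentage_error(pred, gold) == pytest.approx(pe_oracle(pred, gold),
                                                         abs=1e-10)


def test_pe_scale_covariant():
    rng = np.random.default_rng(2)
    p = [[rng.normal(size=30)]]
    g = [[rng.normal(size=30)]]
    scaled_p = [[5.0 * p[0][0]]]
    scaled_g = [[5.0 * g[0][0]]]
    assert percentage_error(scaled_p, scaled_g) == pytest.approx(
        percentage_error(p, g))


def test_pe_flat_gold_raises():
    with pytest.raises(ValueError, match="flat gold"):
        percentage_error([[np.arange(5.0)]], [[np.full(5, 3.0)]])


# ----------------------------------------------------------------- DTW

def dtw_brute_force(g, p):
    """Enumerate every monotone warping path from (0,0) to (n-1,m-1)."""
    n, m = len(g), len(p)
    best = np.inf
    stack = [((0, 0), abs(g[0] - p[0]))]
    while stack:
        (i, j), cost = stack.pop()
        if cost >= best:
            continue
        if (i, j) == (n - 1, m - 1):
            best = min(best, cost)
            continue
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                stack.append(((ni, nj), cost + abs(g[ni] - p[nj])))
    return best


def test_dtw_identical_is_zero():
    a = np.array([1.0, 2.0, 3.0])
    assert dtw_distance(a, a, normalise=False) == 0.0


def test_dtw_single_cell():
    assert dtw_distance(np.array([0.0]), np.array([5.0]), normalise=False) == 5.0
    assert dtw_distance(np.array([0.0]), np.array([5.0]), normalise=True) == 2.5


def test_dtw_small_example():
    g, p = np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0])
    assert dtw_distance(g, p, normalise=False) == pytest.approx(
        dtw_brute_force(g, p))


def test_dtw_matches_brute_force_battery():
    rng = np.random.default_rng(13)
    for _ in range(60):
        n, m = rng.integers(1, 6, size=2)
        g = rng.normal(size=n) * 5
        p = rng.normal(size=m) * 5
        assert dtw_distance(g, p, normalise=False) == pytest.approx(
            dtw_brute_force(g, p), abs=1e-10)


def test_dtw_symmetric():
    rng = np.random.default_rng(19)
    g, p = rng.normal(size=30), rng.normal(size=25)
    assert dtw_distance(g, p) == pytest.approx(dtw_distance(p, g))


def test_dtw_empty_raises():
    with pytest.raises(ValueError):
        dtw_distance(np.array([]), np.array([1.0]))


# -------------------------------------------------------- Bland-Altman

def test_bland_altman_closed_form():
    rep = bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
    assert rep["mean_diff"] == pytest.approx(0.0)
    assert rep["sd_diff"] == pytest.approx(1.0)
    assert rep["loa_low"] == pytest.approx(-1.96)
    assert rep["loa_high"] == pytest.approx(1.96)


def test_bland_altman_identical_pairs():
    rep = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert rep["mean_diff"] == 0.0 and rep["sd_diff"] == 0.0


def test_bland_altman_matches_formula_oracle():
    rng = np.random.default_rng(31)
    gold = rng.uniform(30, 60, size=78)
    d = rng.normal(8, 10, size=78)
    pred = gold + d
    rep = bland_altman(pred, gold)
    n = 78
    mean, sd = d.mean(), d.std(ddof=1)
    tcrit = stats.t.ppf(0.975, n - 1)
    assert rep["mean_diff"] == pytest.approx(mean, abs=1e-10)
    assert rep["sd_diff"] == pytest.approx(sd, abs=1e-10)
    assert rep["loa_high"] == pytest.approx(mean + 1.96 * sd, abs=1e-10)
    assert rep["ci_mean"][0] == pytest.approx(mean - tcrit * sd / np.sqrt(n),
                                              abs=1e-10)
    assert rep["ci_loa_high"][1] == pytest.approx(
        mean + 1.96 * sd + tcrit * sd * np.sqrt(3 / n), abs=1e-10)
    assert rep["loa_low"] <= rep["mean_diff"] <= rep["loa_high"]
    assert 0 <= rep["ks_p"] <= 1


def test_bland_altman_relative_mode():
    rep = bland_altman([11.0, 22.0, 33.0], [10.0, 20.0, 30.0], relative=True)
    assert rep["mean_diff"] == pytest.approx(10.0)
    with pytest.raises(ValueError):
        bland_altman([1.0, 2.0, 3.0], [0.0, 2.0, 3.0], relative=True)


def test_bland_altman_needs_three_pairs():
    with pytest.raises(ValueError):
        bland_altman([1.0, 2.0], [1.0, 2.0])


# ------------------------------------------------- correlation and OLS

def test_regression_identity_line():
    x = np.arange(10.0)
    rep = correlation_regression(x, x)
    assert rep["pearson_r"] == pytest.approx(1.0)
    assert rep["slope"] == pytest.approx(1.0)
    assert rep["intercept"] == pytest.approx(0.0, abs=1e-12)


def test_regression_negative_line():
    x = np.arange(10.0)
    rep = correlation_regression(x, -2 * x + 3)
    assert rep["pearson_r"] == pytest.approx(-1.0)
    assert rep["slope"] == pytest.approx(-2.0)
    assert rep["intercept"] == pytest.approx(3.0)


def test_regression_matches_normal_equations():
    rng = np.random.default_rng(37)
    x = rng.uniform(0, 1, 50)
    y = 0.94 * x + 0.01 + rng.normal(0, 0.05, 50)
    rep = correlation_regression(x, y)
    X = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
    assert rep["slope"] == pytest.approx(slope, abs=1e-10)
    assert rep["intercept"] == pytest.approx(intercept, abs=1e-10)
    r = np.corrcoef(x, y)[0, 1]
    assert rep["pearson_r"] == pytest.approx(r, abs=1e-10)


def test_regression_degenerate_x_raises():
    with pytest.raises(ValueError):
        correlation_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ------------------------------------------------- table aggregation

def test_average_is_mean_of_per_joint_entries():
    """The summary column over (far knee, far hip, near knee, near hip)
    is the plain mean of the four per-joint values."""
    assert aggregate_joint_metrics([4.17, 3.46, 2.94, 2.43]) == pytest.approx(3.25)
    assert aggregate_joint_metrics([25.81, 32.88, 17.33, 25.57]) == pytest.approx(
        25.40, abs=0.005)


def test_relative_improvement_convention():
    assert relative_improvement(3.64, 3.25) == pytest.approx(0.107, abs=5e-4)
    with pytest.raises(ValueError):
        relative_improvement(0.0, 1.0)
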