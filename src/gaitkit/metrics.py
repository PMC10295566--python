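"""Agreement metrics between predicted and gold-standard gait signals.

Two signal-level metrics: the percentage error (PE), per-joint RMSE
normalised by the gold signal's range and averaged over joints then
samples, and the dynamic-time-warping (DTW) distance normalised by total
signal length, which tolerates small temporal misalignments that inflate
pointwise errors.  Parameter-level agreement uses Bland-Altman limits of
agreement, Pearson correlation and ordinary least-squares regression.

Missing samples are substituted before scoring: by the signal mean for
PE (so gaps neither inflate nor deflate the normalised RMSE) and by the
most recent valid value for DTW (which preserves signal shape for the
warping alignment).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .kinematics import AngleSignal


def fill_missing(signal: AngleSignal, mode: str) -> AngleSignal:
    """Substitute NaN samples: ``mean`` of valid samples, or ``locf``.

    ``locf`` carries the most recent valid value forward; a leading gap
    is back-filled with the first valid value.
    """
    theta = signal.theta.copy()
    valid = np.isfinite(theta)
    if not np.any(valid):
        raise ValueError("signal has no valid samples to fill from")
    if mode == "mean":
        theta[~valid] = theta[valid].mean()
    elif mode == "locf":
        first = int(np.argmax(valid))
        theta[:first] = theta[first]
        for t in range(first + 1, len(theta)):
            if not np.isfinite(theta[t]):
                theta[t] = theta[t - 1]
    else:
        raise ValueError(f"mode must be 'mean' or 'locf', got {mode!r}")
    return signal.replace(theta=theta)


def percentage_error(
    pred: Sequence[Sequence[np.ndarray]], gold: Sequence[Sequence[np.ndarray]]
) -> float:
    """Range-normalised RMSE, in percent.

    ``pred`` and ``gold`` are nested as samples x joints x frames.  For
    each (sample, joint) the RMSE over frames is divided by the gold
    signal's range; these ratios are averaged over joints, then over
    samples, and scaled by 100.
    """
    if len(pred) != len(gold) or len(pred) == 0:
        raise ValueError("pred and gold must hold the same nonzero sample count")
    sample_means = []
    for s, (ps, gs) in enumerate(zip(pred, gold)):
        if len(ps) != len(gs) or len(ps) == 0:
            raise ValueError(f"sample {s}: joint counts differ or are zero")
        joint_vals = []
        for j, (p, g) in enumerate(zip(ps, gs)):
            p = np.asarray(p, dtype=float)
            g = np.asarray(g, dtype=float)
            if p.shape != g.shape:
                raise ValueError(f"sample {s} joint {j}: length mismatch")
            rng = float(np.max(g) - np.min(g))
            if rng == 0.0:
                raise ValueError(f"sample {s} joint {j}: flat gold signal has no range")
            rmse = float(np.sqrt(np.mean((p - g) ** 2)))
            joint_vals.append(rmse / rng)
        sample_means.append(np.mean(joint_vals))
    return 100.0 * float(np.mean(sample_means))


def dtw_distance(g: np.ndarray, p: np.ndarray, normalise: bool = True) -> float:
    """Dynamic-time-warping distance with absolute-difference point cost.

    Classic dynamic programme over monotone warping paths anchored at
    both ends; cell (i, j) adds ``|g_i - p_j|`` to the cheapest of its
    three predecessors.  When ``normalise`` is set the result is divided
    by the total length ``len(g) + len(p)`` (2m for equal lengths).
    """
    g = np.asarray(g, dtype=float)
    p = np.asarray(p, dtype=float)
    if g.size == 0 or p.size == 0:
        raise ValueError("empty series")
    n, m = len(g), len(p)
    prev = np.empty(m)
    cur = np.empty(m)
    # first row: only horizontal moves
    np.cumsum(np.abs(g[0] - p), out=prev)
    for i in range(1, n):
        gi = g[i]
        cur[0] = prev[0] + abs(gi - p[0])
        c_left = cur[0]
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if c_left < best:
                best = c_left
            c_left = best + abs(gi - p[j])
            cur[j] = c_left
        prev, cur = cur, prev
    total = float(prev[m - 1])
    return total / (n + m) if normalise else total


def bland_altman(
    pred: Sequence[float], gold: Sequence[float], relative: bool = False
) -> dict:
    """Bland-Altman agreement analysis of paired measurements.

    Differences are ``pred - gold`` (or ``100 * (pred - gold) / gold``
    in relative mode).  Reports the mean difference, its SD, the 95 %
    limits of agreement (mean +- 1.96 SD), t-based 95 % confidence
    intervals for the mean and for each limit (SE of a limit taken as
    ``sd * sqrt(3/n)``), and a Kolmogorov-Smirnov normality p-value of
    the standardised differences.
    """
    pred = np.asarray(pred, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if pred.shape != gold.shape or pred.ndim != 1:
        raise ValueError("pred and gold must be equal-length 1-D arrays")
    n = len(pred)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if relative:
        if np.any(gold == 0):
            raise ValueError("relative differences undefined for zero gold values")
        d = 100.0 * (pred - gold) / gold
    else:
        d = pred - gold
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff
    tcrit = float(stats.t.ppf(0.975, n - 1))
    se_mean = sd_diff / np.sqrt(n)
    se_loa = sd_diff * np.sqrt(3.0 / n)
    if sd_diff > 0:
        ks_p = float(stats.kstest((d - mean_diff) / sd_diff, "norm").pvalue)
    else:
        ks_p = float("nan")
    return {
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "loa_low": loa_low,
        "loa_high": loa_high,
        "ci_mean": (mean_diff - tcrit * se_mean, mean_diff + tcrit * se_mean),
        "ci_loa_low": (loa_low - tcrit * se_loa, loa_low + tcrit * se_loa),
        "ci_loa_high": (loa_high - tcrit * se_loa, loa_high + tcrit * se_loa),
        "ks_p": ks_p,
        "n": n,
        "relative": relative,
    }


def correlation_regression(x: Sequence[float], y: Sequence[float]) -> dict:
    """Pearson r and OLS regression of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    if np.std(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    res = stats.linregress(x, y)
    return {"pearson_r": float(res.rvalue), "slope": float(res.slope),
            "intercept": float(res.intercept)}


def aggregate_joint_metrics(per_joint: Sequence[float]) -> float:
    """Row average over per-joint metric values (plain mean)."""
    vals = np.asarray(list(per_joint), dtype=float)
    if vals.size == 0:
        raise ValueError("no per-joint values")
    return float(vals.mean())


def relative_improvement(baseline: float, improved: float) -> float:
    """Fractional reduction of a metric: (baseline - improved) / baseline."""
    if baseline == 0:
        raise ValueError("baseline metric is zero")
    return (baseline - improved) / baseline
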