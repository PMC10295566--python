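"""Frequency-domain denoising by least-RMSE DFT component selection.

After Kalman filtering, a burn-in prefix (the filter needs time to
converge) is dropped and the signal is reduced to the N discrete-Fourier
components whose retention reconstructs it with the least RMS error.
For a real signal that is, by Parseval's theorem, equivalent to keeping
the N components of largest combined spectral energy: DC counts its own
energy, and each conjugate pair counts as a single component with twice
the energy of its positive-frequency half.  Gait signals being
quasi-periodic sums of a few cosines, N = 5 (DC plus about four
harmonics) captures them while rejecting broadband noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .kinematics import AngleSignal

logger = logging.getLogger(__name__)


@dataclass
class SpectrumSelection:
    """Retained spectral components of a real signal.

    ``m`` is the analysed length; ``selected`` holds nonnegative
    frequency bin indices (conjugate halves implied); ``coefficients``
    are the corresponding one-sided DFT values; ``fs`` is the sampling
    rate in Hz.
    """

    m: int
    selected: np.ndarray
    coefficients: np.ndarray
    fs: float

    def frequencies(self) -> np.ndarray:
        """Frequencies in Hz of the selected bins."""
        return self.selected * self.fs / self.m


def apply_cut(signal: AngleSignal, cut: float) -> AngleSignal:
    """Drop the leading ``floor(cut * len)`` frames of a signal."""
    if not 0 <= cut < 1:
        raise ValueError("cut must lie in [0, 1)")
    n = len(signal)
    drop = math.floor(cut * n)
    if n - drop < 2:
        raise ValueError(f"cut of {drop} frames leaves fewer than 2 of {n}")
    return signal.replace(theta=signal.theta[drop:].copy(),
                          visibility=signal.visibility[drop:].copy())


def _energy_weights(spectrum: np.ndarray, m: int) -> np.ndarray:
    """Parseval energy contribution of each one-sided bin."""
    w = np.abs(spectrum) ** 2
    # interior bins represent a conjugate pair -> double energy
    pair = np.ones_like(w)
    pair[1:] = 2.0
    if m % 2 == 0:
        pair[-1] = 1.0  # Nyquist bin is its own conjugate
    return w * pair


def lrmse_select(theta: np.ndarray, n_components: int, fs: float = 1.0) -> SpectrumSelection:
    """Select the N components minimising reconstruction RMSE.

    DC is eligible and each conjugate pair counts once.  Ties in energy
    are broken toward the lower frequency index, so the selection is
    deterministic.  If N meets or exceeds the number of distinct
    components, all are returned (with a logged note).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1 or len(theta) < 2:
        raise ValueError("theta must be a 1-D series of length >= 2")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite (filter before denoising)")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    m = len(theta)
    spectrum = np.fft.rfft(theta)
    n_bins = len(spectrum)
    if n_components >= n_bins:
        logger.info("requested %d components but only %d exist; keeping all",
                    n_components, n_bins)
        selected = np.arange(n_bins)
    else:
        weights = _energy_weights(spectrum, m)
        # stable sort on (-energy, index): largest energy first, lower
        # index wins ties
        order = np.lexsort((np.arange(n_bins), -weights))
        selected = np.sort(order[:n_components])
    return SpectrumSelection(m=m, selected=selected,
                             coefficients=spectrum[selected], fs=fs)


def reconstruct(selection: SpectrumSelection) -> np.ndarray:
    """Inverse transform of the selected components only (real output)."""
    half = np.zeros(selection.m // 2 + 1, dtype=complex)
    half[selection.selected] = selection.coefficients
    return np.fft.irfft(half, n=selection.m)


def fdf_filter(signal: AngleSignal, config: PipelineConfig) -> AngleSignal:
    """Cut the burn-in prefix, then keep the N least-RMSE components.

    Expects a gap-free (already Kalman-filtered) signal.  The output has
    the post-cut length and visibility 1 everywhere: it is a model
    reconstruction, not a gated measurement.
    """
    trimmed = apply_cut(signal, config.cut)
    selection = lrmse_select(trimmed.theta, config.n_components, fs=signal.fps)
    theta = reconstruct(selection)
    return trimmed.replace(theta=theta, visibility=np.ones_like(theta))


def dominant_frequency(selection: SpectrumSelection) -> float:
    """Frequency (Hz) of the strongest selected non-DC component.

    Ties go to the lower frequency.  Raises if only DC was selected —
    the signal then carries no periodicity to report.
    """
    non_dc = selection.selected > 0
    if not np.any(non_dc):
        raise ValueError("selection contains no non-DC component; no periodicity")
    idx = selection.selected[non_dc]
    coeffs = selection.coefficients[non_dc]
    w = _energy_weights_at(coeffs, idx, selection.m)
    total = float(np.sum(np.abs(selection.coefficients) ** 2))
    if total == 0.0 or np.max(w) <= 1e-20 * total:
        raise ValueError("non-DC components are numerically null; no periodicity")
    order = np.lexsort((idx, -w))
    return float(idx[order[0]] * selection.fs / selection.m)


def _energy_weights_at(coeffs: np.ndarray, idx: np.ndarray, m: int) -> np.ndarray:
    w = np.abs(coeffs) ** 2
    pair = np.where((idx > 0) & ~((m % 2 == 0) & (idx == m // 2)), 2.0, 1.0)
    return w * pair
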