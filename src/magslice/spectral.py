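"""Temporal bandwidth analysis: cumulative signal power, Butterworth
low-pass filtering and Nyquist sampling-rate recommendation.

The cumulative power curve answers the acquisition question "what fraction
of the signal's (AC) power lies below frequency f?"; the frequency at which
it crosses a chosen threshold, doubled, is the recommended sampling rate.
The PSD is a plain (rectangular-window) periodogram with the DC component
excluded -- evoked transients are compactly supported, so spectral leakage
is negligible, and the rectangular window preserves Parseval's identity
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpectrumSummary",
    "cumulative_power",
    "butterworth_lowpass",
    "recommended_sampling_rate",
]


@dataclass
class SpectrumSummary:
    """One-sided cumulative power fraction over frequency."""

    frequencies: np.ndarray  # Hz, DC excluded
    cumulative_power_fraction: np.ndarray  # non-decreasing, ends at 1
    fs_signal: float  # Hz
    total_power: float  # variance of the signal (units^2)

    def f_cutoff_at(self, threshold: float) -> float:
        """Smallest frequency whose cumulative power fraction >= threshold."""
        if not 0 < threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        idx = int(np.searchsorted(self.cumulative_power_fraction, threshold))
        idx = min(idx, self.frequencies.size - 1)
        return float(self.frequencies[idx])

    def recommended_fs(self, threshold: float = 0.95) -> float:
        return 2.0 * self.f_cutoff_at(threshold)


def cumulative_power(signal, fs_signal: float) -> SpectrumSummary:
    """Cumulative fraction of AC signal power below each frequency.

    The total power is the time-domain variance (Parseval); a constant
    signal has no AC power and is rejected.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 16:
        raise ValueError("signal must be 1-D with at least 16 samples")
    if fs_signal <= 0:
        raise ValueError("fs_signal must be > 0")
    freqs, psd = sps.periodogram(
        x, fs=fs_signal, window="boxcar", detrend="constant", scaling="density"
    )
    freqs, psd = freqs[1:], psd[1:]  # exclude DC
    total = psd.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("signal has zero AC power (constant input)")
    frac = np.cumsum(psd) / total
    df = freqs[1] - freqs[0] if freqs.size > 1 else fs_signal / x.size
    return SpectrumSummary(
        frequencies=freqs,
        cumulative_power_fraction=frac,
        fs_signal=float(fs_signal),
        total_power=float(total * df),
    )


def butterworth_lowpass(
    signal, fc: float, fs_signal: float, order: int = 3, zero_phase: bool = False
) -> np.ndarray:
    """Third-order (by default) Butterworth low-pass filter.

    Causal single-pass by default, matching a real-time acquisition chain;
    ``zero_phase`` applies the filter forward and backward instead.
    """
    x = np.asarray(signal, dtype=float)
    if not 0 < fc < fs_signal / 2:
        raise ValueError("fc must lie in (0, fs_signal/2)")
    sos = sps.butter(order, fc, btype="low", fs=fs_signal, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def recommended_sampling_rate(summary: SpectrumSummary, power_threshold: float = 0.95) -> float:
    """Nyquist rate for the cumulative-power cutoff: ``2 * f_cutoff``."""
    return summary.recommended_fs(power_threshold)
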