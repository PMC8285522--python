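"""Trace conditioning: low-pass filtering, windowing, noise estimation.

Raw height-spectroscopy data are acquired at ~500–600 kHz and low-pass
filtered to an effective 20 kHz bandwidth before state detection; slow
baseline drift is handled by cutting the trace into 0.4–0.6 s windows that
are idealized independently.  The filter is a zero-phase Gaussian whose
−3 dB point sits at the requested corner frequency — the analysis is
offline, so no causal filter (and no phase distortion of dwell boundaries)
is needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .trace import TimeTrace

__all__ = [
    "lowpass_filter",
    "gaussian_sigma_samples",
    "noise_oversampling",
    "lag1_autocorrelation",
    "segment_trace",
    "estimate_noise_sigma",
    "NoiseEstimate",
]

log = logging.getLogger(__name__)


def gaussian_sigma_samples(cutoff_hz: float, sample_rate: float) -> float:
    """Gaussian kernel width (in samples) with −3 dB at ``cutoff_hz``.

    The Gaussian's transfer function is exp(−2π²σ_t²f²); solving
    |H(fc)|² = 1/2 gives σ_t = sqrt(ln 2)/(2π fc).
    """
    sigma_t = math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff_hz)
    return sigma_t * sample_rate


def noise_oversampling(cutoff_hz: float, sample_rate: float) -> float:
    """Effective oversampling factor g of Gaussian-filtered white noise.

    After low-pass filtering, neighbouring samples are correlated and the
    variance of an n-sample mean is σ²·g/n rather than σ²/n; equivalently
    the trace carries only n/g independent samples.  For a Gaussian kernel
    of width σ_s samples, g = 1/Σk² = 2·σ_s·√π (floored at 1 for
    negligible filtering).
    """
    sigma_s = gaussian_sigma_samples(cutoff_hz, sample_rate)
    return max(2.0 * sigma_s * math.sqrt(math.pi), 1.0)


def lag1_autocorrelation(cutoff_hz: float, sample_rate: float) -> float:
    """Lag-1 autocorrelation of Gaussian-filtered white noise.

    The autocorrelation of the filtered noise is Gaussian with width
    σ_s·√2, so ρ(1) = exp(−1/(4σ_s²)).  Used to undo the shrinkage of
    the first-difference (Haar/MAD) noise estimator on filtered traces:
    σ_marginal = σ_haar / √(1 − ρ(1)).
    """
    sigma_s = gaussian_sigma_samples(cutoff_hz, sample_rate)
    if sigma_s <= 0:
        return 0.0
    return min(math.exp(-1.0 / (4.0 * sigma_s ** 2)), 1.0 - 1e-12)


def lowpass_filter(trace: TimeTrace, cutoff_hz: float) -> TimeTrace:
    """Zero-phase Gaussian low-pass with −3 dB point at ``cutoff_hz``.

    Length preserving, unit DC gain (reflect boundary handling).
    """
    nyquist = trace.sample_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff must be in (0, Nyquist={nyquist:g} Hz), got {cutoff_hz:g}")
    sigma = gaussian_sigma_samples(cutoff_hz, trace.sample_rate)
    out = ndimage.gaussian_filter1d(trace.values, sigma, mode="reflect")
    return trace.replace_values(out, lowpass_hz=cutoff_hz)


def segment_trace(trace: TimeTrace, window_s: float = 0.5):
    """Cut a trace into non-overlapping contiguous windows.

    A trailing partial window is kept if it is at least half the requested
    length, otherwise dropped (set ``window_s`` >= duration to disable).
    Each segment records its sample offset in ``metadata["offset_samples"]``.
    """
    if not window_s > 0:
        raise ValueError("window must be > 0")
    n = trace.n_samples
    win = int(round(window_s * trace.sample_rate))
    if win > n:
        log.warning("window (%g s) longer than trace (%g s); "
                    "returning a single segment", window_s, trace.duration)
        win = n
    segments = []
    start = 0
    while start < n:
        stop = min(start + win, n)
        length = stop - start
        if length < win and length < win / 2.0:
            break  # drop short tail
        segments.append(trace.replace_values(
            trace.values[start:stop], offset_samples=start))
        start = stop
    return segments


@dataclass
class NoiseEstimate:
    """Robust noise level of a trace (signal units)."""
    sigma: float
    method: str = "haar_mad"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def estimate_noise_sigma(trace: TimeTrace) -> NoiseEstimate:
    """Estimate the noise standard deviation from first differences.

    sigma = median(|x_{i+1} − x_i|) / (0.6745 · √2) — the Haar/MAD
    estimator.  Because state transitions contribute to only a small
    fraction of the difference pairs, the median is insensitive to the
    discrete steps, and a constant offset or slow drift cancels in the
    differences.
    """
    if trace.n_samples < 16:
        raise ValueError("need at least 16 samples to estimate noise")
    diffs = np.abs(np.diff(trace.values))
    sigma = float(np.median(diffs)) / (0.6745 * math.sqrt(2.0))
    return NoiseEstimate(sigma=sigma)
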