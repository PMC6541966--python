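"""Windowed PSD estimation, dB conversion, and spectral smoothing.

The spectrogram is a Welch-style short-time PSD: Hann-tapered windows of
1024 samples (~1 s at 1 kHz, ~0.977 Hz bin spacing) with 50% overlap and
density scaling, restricted to the 2-45 Hz analysis range. Power is
expressed as 10*log10(PSD) after flooring at 1e-12 so the dB field is
finite everywhere, then smoothed along the frequency axis with a Gaussian
kernel of ``smooth_width_bins`` points (MATLAB ``gausswin`` shape:
``sigma = (width - 1) / 5`` bins), renormalized at the range edges so the
kernel mass is unity everywhere. The narrow kernel smooths within a band
without bleeding a band-limited oscillation into its neighbours.

Windows are not zero-padded; a partial trailing window is dropped. Each
window is stamped with its center time, anchored at recording start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .io import LfpRecording

__all__ = ["SpectralConfig", "SpectrogramResult", "spectrogram", "mean_psd",
           "EmptyPhaseError"]


class EmptyPhaseError(ValueError):
    """A requested time interval contains no spectrogram window centers."""


@dataclass(frozen=True)
class SpectralConfig:
    window_samples: int = 1024
    overlap_fraction: float = 0.5
    freq_range_hz: tuple[float, float] = (2.0, 45.0)
    db_floor: float = 1e-12
    smooth_width_bins: int = 3  # Gaussian kernel length along frequency; <=1 disables

    def validate(self) -> None:
        n = self.window_samples
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError(f"window_samples must be a power of two, got {n}")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        lo, hi = self.freq_range_hz
        if not (0 <= lo < hi):
            raise ValueError(f"invalid freq_range_hz {self.freq_range_hz}")
        if self.db_floor <= 0:
            raise ValueError("db_floor must be positive")

    @property
    def hop_samples(self) -> int:
        return int(round(self.window_samples * (1 - self.overlap_fraction)))


@dataclass(frozen=True)
class SpectrogramResult:
    """Time-frequency power matrix in decibels over the analysis range."""

    time_bins_s: np.ndarray   # window-center times, seconds
    freq_bins_hz: np.ndarray  # bin centers within freq_range
    power_db: np.ndarray      # (time, frequency)

    def __post_init__(self) -> None:
        if self.power_db.shape != (self.time_bins_s.size, self.freq_bins_hz.size):
            raise ValueError("power_db shape inconsistent with axes")
        if not np.all(np.isfinite(self.power_db)):
            raise ValueError("power_db contains non-finite values")

    @property
    def freq_resolution_hz(self) -> float:
        return float(np.diff(self.freq_bins_hz).mean()) if self.freq_bins_hz.size > 1 else np.nan


def _gaussian_smooth_freq(power_db: np.ndarray, width_bins: int) -> np.ndarray:
    # Zero-padded convolution divided by the in-range kernel mass: unit-sum
    # kernel in the interior, renormalized at the edges. Kernel shape follows
    # MATLAB's gausswin(width): sigma = (width - 1) / (2 * 2.5).
    if width_bins <= 1:
        return power_db
    radius = (int(width_bins) - 1) // 2
    sigma = max((int(width_bins) - 1) / 5.0, 1e-12)
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()
    num = ndimage.convolve1d(power_db, kernel, axis=-1, mode="constant", cval=0.0)
    den = ndimage.convolve1d(
        np.ones(power_db.shape[-1]), kernel, mode="constant", cval=0.0
    )
    return num / den


def spectrogram(
    recording: LfpRecording, config: SpectralConfig = SpectralConfig()
) -> SpectrogramResult:
    """Short-time Hann-tapered PSD of a recording, in dB.

    Raises ``ValueError`` if the recording is shorter than one window;
    callers handling sub-window segments (short stimulus phases) should
    recompute with a smaller power-of-two window instead.
    """
    config.validate()
    n = config.window_samples
    if recording.n_samples < n:
        raise ValueError(
            f"recording has {recording.n_samples} samples, shorter than one "
            f"{n}-sample window"
        )
    noverlap = n - config.hop_samples
    freqs, times, psd = signal.spectrogram(
        recording.samples,
        fs=recording.sampling_rate,
        window="hann",
        nperseg=n,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
    )
    lo, hi = config.freq_range_hz
    keep = (freqs >= lo) & (freqs <= hi)
    power_db = 10.0 * np.log10(np.maximum(psd[keep].T, config.db_floor))
    power_db = _gaussian_smooth_freq(power_db, config.smooth_width_bins)
    return SpectrogramResult(
        time_bins_s=times, freq_bins_hz=freqs[keep], power_db=power_db
    )


def mean_psd(spec: SpectrogramResult, time_window_s: tuple[float, float]) -> np.ndarray:
    """Mean dB spectrum over windows whose centers fall in [start, end)."""
    start, end = time_window_s
    mask = (spec.time_bins_s >= start) & (spec.time_bins_s < end)
    if not mask.any():
        raise EmptyPhaseError(
            f"no spectrogram window centers inside [{start}, {end}) s"
        )
    return spec.power_db[mask].mean(axis=0)
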