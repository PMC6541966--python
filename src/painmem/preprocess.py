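"""Zero-phase band-limiting of raw LFP to the 2-45 Hz analysis band.

The analysis filter is a 4th-order Butterworth bandpass applied forward
and backward (noncausal, zero net phase), so the effective magnitude
response is |H(f)|^2 of the order-4 design. Edge transients are
suppressed by odd-symmetric signal extension before filtering (scipy's
``sosfiltfilt`` default, ``padtype='odd'``).

The acquisition-side 0.3-250 Hz hardware band limit is a property of the
recording, not of the analysis, and is never re-applied here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import LfpRecording

__all__ = ["FilterSpec", "bandpass", "magnitude_response"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass design parameters.

    ``order`` counts the poles of the bandpass prototype; the
    forward-backward application doubles the effective magnitude order.
    """

    low_hz: float = 2.0
    high_hz: float = 45.0
    order: int = 4

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band edges must satisfy 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )
        if self.high_hz >= nyquist:
            raise ValueError(
                f"high edge {self.high_hz} Hz at or above Nyquist {nyquist} Hz"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def sos(self, sampling_rate: float) -> np.ndarray:
        self.validate(sampling_rate)
        return signal.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass",
            fs=sampling_rate, output="sos",
        )


def bandpass(recording: LfpRecording, spec: FilterSpec = FilterSpec()) -> LfpRecording:
    """Apply the zero-phase bandpass; output has the same length and rate."""
    sos = spec.sos(recording.sampling_rate)
    filtered = signal.sosfiltfilt(sos, recording.samples, padtype="odd")
    return LfpRecording(
        samples=filtered,
        sampling_rate=recording.sampling_rate,
        channel_id=recording.channel_id,
        units=recording.units,
    )


def magnitude_response(
    spec: FilterSpec, freqs_hz: np.ndarray, sampling_rate: float
) -> np.ndarray:
    """Effective amplitude gain |H(f)|^2 of the forward-backward filter.

    This is the analytic oracle for what :func:`bandpass` does to a
    sinusoid of frequency f: the single-pass magnitude squared.
    """
    sos = spec.sos(sampling_rate)
    _, h = signal.sosfreqz(
        sos, worN=np.atleast_1d(np.asarray(freqs_hz, float)), fs=sampling_rate
    )
    return np.abs(h) ** 2
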