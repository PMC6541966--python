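"""Event-aligned phase segmentation and per-band mean-PSD extraction.

Each stimulation trial is segmented into a prestimulus window (the 5 s
before probe onset), a stimulus window (onset until paw withdrawal) and a
poststimulus window. The mean dB power of each canonical frequency band
within each phase is the quantity all downstream contrasts compare.

Band tiling of the 2-45 Hz range (half-open, gamma closed at 45 Hz):
delta [2, 4), theta [4, 9), alpha [9, 15), beta [15, 30), gamma [30, 45].
A spectrogram bin belongs to a band iff ``low <= bin_center < high``; a
spectrogram window belongs to a phase iff its center time lies in the
phase's half-open interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EventTable, LfpRecording
from .spectral import SpectralConfig, SpectrogramResult, spectrogram

__all__ = [
    "BandDefinition",
    "BANDS",
    "PhaseWindows",
    "segment_phases",
    "band_phase_means",
    "compartment_phase_means",
    "RAMP_DURATION_S",
    "MIN_SHORT_PHASE_SAMPLES",
]

logger = logging.getLogger(__name__)

#: Probe force ramp duration (s): trials without a recorded withdrawal get a
#: stimulus window truncated at onset + this value, and are flagged.
RAMP_DURATION_S = 20.0

#: Shortest segment for the single-window fallback PSD of a sub-window phase.
MIN_SHORT_PHASE_SAMPLES = 256

PHASES = ("prestimulus", "stimulus", "poststimulus")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float
    closed_high: bool = False

    def contains(self, freq_hz: np.ndarray) -> np.ndarray:
        upper = freq_hz <= self.high_hz if self.closed_high else freq_hz < self.high_hz
        return (freq_hz >= self.low_hz) & upper


BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 9.0),
    BandDefinition("alpha", 9.0, 15.0),
    BandDefinition("beta", 15.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0, closed_high=True),
)


@dataclass(frozen=True)
class PhaseWindows:
    """Half-open phase intervals per trial.

    Backed by a DataFrame with columns ``trial_id``, ``phase``, ``start_s``,
    ``end_s``, ``flagged`` (True when the stimulus end was imputed from the
    ramp duration because no withdrawal was recorded).
    """

    frame: pd.DataFrame

    def intervals(self, trial_id: str) -> dict[str, tuple[float, float]]:
        rows = self.frame[self.frame["trial_id"] == trial_id]
        return {
            r.phase: (float(r.start_s), float(r.end_s)) for r in rows.itertuples()
        }


def segment_phases(
    events: EventTable,
    prestim_s: float = 5.0,
    poststim_s: float = 5.0,
    recording_duration_s: float | None = None,
) -> PhaseWindows:
    """Build per-trial phase windows from an event table.

    Trials whose onset is closer than ``prestim_s`` to the recording start
    are excluded (logged); trials lacking a withdrawal get a stimulus
    window truncated at onset + 20 s (the probe ramp length) and are
    flagged. Poststimulus windows are clipped to the recording end when a
    duration is supplied.
    """
    rows = []
    for trial_id in events.trial_ids:
        onset = events.onset(trial_id)
        if onset - prestim_s < 0:
            logger.warning(
                "trial %s excluded: onset %.3f s leaves no room for the "
                "%.1f s prestimulus window", trial_id, onset, prestim_s,
            )
            continue
        withdrawal = events.withdrawal(trial_id)
        flagged = withdrawal is None
        stim_end = onset + RAMP_DURATION_S if flagged else withdrawal
        if flagged:
            logger.warning(
                "trial %s: no paw_withdrawal event; stimulus window truncated "
                "at onset + %.0f s", trial_id, RAMP_DURATION_S,
            )
        post_end = stim_end + poststim_s
        if recording_duration_s is not None:
            post_end = min(post_end, recording_duration_s)
        rows.append((trial_id, "prestimulus", onset - prestim_s, onset, flagged))
        rows.append((trial_id, "stimulus", onset, stim_end, flagged))
        if post_end > stim_end:
            rows.append((trial_id, "poststimulus", stim_end, post_end, flagged))
    frame = pd.DataFrame(
        rows, columns=["trial_id", "phase", "start_s", "end_s", "flagged"]
    )
    return PhaseWindows(frame)


def _short_phase_psd(
    recording: LfpRecording,
    config: SpectralConfig,
    start_s: float,
    end_s: float,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Single-window PSD fallback for phases shorter than one window.

    The window is the phase length rounded down to a power of two, at least
    256 samples; shorter phases return ``None``.
    """
    fs = recording.sampling_rate
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
    n_avail = min(i1, recording.n_samples) - max(i0, 0)
    if n_avail < MIN_SHORT_PHASE_SAMPLES:
        return None
    n = 2 ** int(math.floor(math.log2(n_avail)))
    n = max(n, MIN_SHORT_PHASE_SAMPLES)
    sub = LfpRecording(
        samples=recording.samples[max(i0, 0): max(i0, 0) + n],
        sampling_rate=fs,
        channel_id=recording.channel_id,
        units=recording.units,
    )
    sub_cfg = SpectralConfig(
        window_samples=n,
        overlap_fraction=0.0,
        freq_range_hz=config.freq_range_hz,
        db_floor=config.db_floor,
        smooth_width_bins=config.smooth_width_bins,
    )
    spec = spectrogram(sub, sub_cfg)
    return spec.freq_bins_hz, spec.power_db.mean(axis=0)


def _band_means_from_spectrum(
    freq_bins_hz: np.ndarray,
    mean_db: np.ndarray,
    bands: tuple[BandDefinition, ...],
) -> dict[str, float]:
    out = {}
    for band in bands:
        mask = band.contains(freq_bins_hz)
        if mask.any():
            out[band.name] = float(mean_db[mask].mean())
    return out


def band_phase_means(
    spec: SpectrogramResult,
    phases: PhaseWindows,
    bands: tuple[BandDefinition, ...] = BANDS,
    recording: LfpRecording | None = None,
    config: SpectralConfig | None = None,
) -> pd.DataFrame:
    """Mean dB power per trial x phase x band.

    For each phase window, windows are selected by center time; a phase
    containing no window center is recomputed from ``recording`` with a
    single shorter window when possible (see :func:`_short_phase_psd`),
    and otherwise omitted with a warning.
    """
    rows = []
    for rec in phases.frame.itertuples():
        interval = (float(rec.start_s), float(rec.end_s))
        mask = (spec.time_bins_s >= interval[0]) & (spec.time_bins_s < interval[1])
        if mask.any():
            freq, mean_db = spec.freq_bins_hz, spec.power_db[mask].mean(axis=0)
        elif recording is not None and config is not None:
            fallback = _short_phase_psd(recording, config, *interval)
            if fallback is None:
                logger.warning(
                    "trial %s phase %s dropped: %.3f s too short for the "
                    "minimum %d-sample window",
                    rec.trial_id, rec.phase, interval[1] - interval[0],
                    MIN_SHORT_PHASE_SAMPLES,
                )
                continue
            freq, mean_db = fallback
        else:
            logger.warning(
                "trial %s phase %s omitted: no spectrogram window centers in "
                "[%.3f, %.3f) s and no recording supplied for recomputation",
                rec.trial_id, rec.phase, *interval,
            )
            continue
        for band_name, value in _band_means_from_spectrum(freq, mean_db, bands).items():
            rows.append((rec.trial_id, rec.phase, band_name, value))
    return pd.DataFrame(rows, columns=["trial_id", "phase", "band", "mean_psd_db"])


def compartment_phase_means(
    spec: SpectrogramResult,
    occupancy_intervals: list[tuple[float, float]],
    bands: tuple[BandDefinition, ...] = BANDS,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Band means over arbitrary occupancy intervals (CPA-session LFPs).

    Same contract as :func:`band_phase_means` with occupancy intervals in
    place of trial phases; rows are labeled by interval.
    """
    labels = labels or [f"interval_{i}" for i in range(len(occupancy_intervals))]
    rows = []
    for label, (start, end) in zip(labels, occupancy_intervals):
        mask = (spec.time_bins_s >= start) & (spec.time_bins_s < end)
        if not mask.any():
            logger.warning(
                "interval %s omitted: no window centers in [%.3f, %.3f) s",
                label, start, end,
            )
            continue
        mean_db = spec.power_db[mask].mean(axis=0)
        for band_name, value in _band_means_from_spectrum(
            spec.freq_bins_hz, mean_db, bands
        ).items():
            rows.append((label, "occupancy", band_name, value))
    return pd.DataFrame(rows, columns=["trial_id", "phase", "band", "mean_psd_db"])
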