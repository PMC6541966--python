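"""Synthetic LFP sessions and behavioral cohorts with seeded determinism.

The generator provides inputs with the statistical structure the analysis
pipeline assumes, so every stage can be exercised and calibrated without
in vivo recordings:

* LFP = 1/f^beta colored noise plus band-limited sinusoids whose
  amplitudes switch between a prestimulus and a stimulus level at each
  trial's probe-onset and paw-withdrawal events (100 ms raised-cosine
  ramps at the transitions avoid spectral splatter).
* Paw-withdrawal-threshold (PWT) trajectories for control / model / EA
  groups across six timepoints, five probe readings per timepoint.
* Conditioned-place-aversion (CPA) compartment occupancies across five
  test days.

The default group-mean tables are synthetic calibration values chosen to
reproduce the qualitative ordering the study design implies (hyperalgesia
in the model group, partial rescue under electroacupuncture, aversion of
the pain-paired compartment after the second injury); they are not
measured values.

Randomness: a master ``numpy.random.SeedSequence`` is spawned into one
child stream per generated object, in a fixed documented order, so the
outputs are independent of generation order and bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BANDS
from .io import EventTable, LfpRecording

__all__ = [
    "BandSchedule",
    "SessionConfig",
    "BehaviorDesign",
    "ConfigurationError",
    "generate_session",
    "generate_behavior",
    "colored_noise",
    "DEFAULT_PWT_MEANS",
    "DEFAULT_CPA_PAIN_MEANS",
    "PWT_TIMEPOINTS",
    "CPA_DAYS",
    "GROUPS",
]

GROUPS = ("control", "model", "EA")
PWT_TIMEPOINTS = ("-1d", "4h", "1d", "5d", "13d", "15d")
CPA_DAYS = ("baseline", "1", "5", "13", "15")

_BAND_INTERVALS = {b.name: (b.low_hz, b.high_hz) for b in BANDS}

# Synthetic calibration tables (grams / seconds). These are invented
# defaults that realize the study's qualitative group-by-time pattern:
# model and EA thresholds collapse 4 h after the first injury, the model
# group stays low and relapses at day 15 after the second injury, EA
# recovers faster and is protected at day 15; CPA pain-paired occupancy
# drops sharply only for the model group at day 15.
DEFAULT_PWT_MEANS: dict[str, tuple[float, ...]] = {
    "control": (38.0, 37.0, 38.0, 38.0, 38.0, 38.0),
    "model": (38.0, 16.0, 20.0, 26.0, 36.0, 20.0),
    "EA": (38.0, 17.0, 28.0, 33.0, 37.0, 34.0),
}
DEFAULT_CPA_PAIN_MEANS: dict[str, dict[str, float]] = {
    "control": {"baseline": 900.0, "1": 880.0, "5": 890.0, "13": 900.0, "15": 890.0},
    "model": {"baseline": 900.0, "1": 850.0, "5": 870.0, "13": 890.0, "15": 600.0},
    "EA": {"baseline": 900.0, "1": 860.0, "5": 880.0, "13": 890.0, "15": 870.0},
}


class ConfigurationError(ValueError):
    """A generator configuration violates an invariant; names the field."""


@dataclass(frozen=True)
class BandSchedule:
    """One oscillatory component with phase-dependent amplitude."""

    band_name: str
    center_freq: float
    prestim_amplitude: float
    stim_amplitude: float

    def __post_init__(self) -> None:
        if self.band_name not in _BAND_INTERVALS:
            raise ConfigurationError(
                f"band_name: unknown band {self.band_name!r}"
            )
        low, high = _BAND_INTERVALS[self.band_name]
        if not (low <= self.center_freq < high):
            raise ConfigurationError(
                f"center_freq: {self.center_freq} Hz outside {self.band_name} "
                f"band [{low}, {high})"
            )
        for name in ("prestim_amplitude", "stim_amplitude"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ConfigurationError(f"{name}: must be finite and >= 0")


@dataclass(frozen=True)
class SessionConfig:
    """Timeline and signal model for one simulated recording session."""

    n_trials: int = 20
    sampling_rate: float = 1000.0
    prestim_duration: float = 5.0
    withdrawal_latency_range: tuple[float, float] = (2.0, 8.0)
    poststim_duration: float = 5.0
    inter_trial_pad: float = 1.5  # noise-only padding between epochs, >= 1 s
    noise_exponent: float = 1.0   # 1/f^beta slope
    noise_scale: float = 1.0      # std of the additive colored noise
    band_schedules: tuple[BandSchedule, ...] = (
        BandSchedule("theta", 6.0, 1.0, 0.5),
    )
    seed: int = 0
    ramp_duration: float = 0.1    # raised-cosine amplitude transition, s

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigurationError("n_trials: must be >= 1")
        highest_edge = max(high for _, high in _BAND_INTERVALS.values())
        if self.sampling_rate <= 2 * highest_edge:
            raise ConfigurationError(
                f"sampling_rate: {self.sampling_rate} Hz must exceed twice the "
                f"highest band edge ({2 * highest_edge:.0f} Hz)"
            )
        lo, hi = self.withdrawal_latency_range
        if not (0 < lo <= hi <= 20.0):
            raise ConfigurationError(
                "withdrawal_latency_range: need 0 < min <= max <= 20 s "
                "(the probe ramp lasts 20 s)"
            )
        if not self.band_schedules:
            raise ConfigurationError("band_schedules: must not be empty")
        if self.inter_trial_pad < 1.0:
            raise ConfigurationError("inter_trial_pad: must be >= 1 s")
        if self.noise_exponent < 0:
            raise ConfigurationError("noise_exponent: must be >= 0")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale: must be >= 0")


def colored_noise(
    n_samples: int, beta: float, rng: np.random.Generator, std: float = 1.0
) -> np.ndarray:
    """1/f^beta noise via frequency-domain shaping of white Gaussian noise.

    The returned trace is normalized to the requested standard deviation
    (zero ``std`` short-circuits to zeros).
    """
    if std == 0 or n_samples == 0:
        return np.zeros(n_samples)
    white = rng.standard_normal(n_samples)
    if beta == 0:
        return std * white / white.std()
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    shaped = np.fft.irfft(spectrum * shaping, n=n_samples)
    return std * shaped / shaped.std()


def _smooth_envelope(step_env: np.ndarray, ramp_samples: int) -> np.ndarray:
    """Convert step transitions into raised-cosine ramps of the given length."""
    if ramp_samples < 2:
        return step_env
    kernel = np.hanning(ramp_samples + 2)[1:-1]
    kernel /= kernel.sum()
    padded = np.pad(step_env, (ramp_samples, ramp_samples), mode="edge")
    return np.convolve(padded, kernel, mode="same")[ramp_samples:-ramp_samples]


def generate_session(config: SessionConfig) -> tuple[LfpRecording, EventTable]:
    """Simulate one continuous recording with its event table.

    The trace concatenates ``n_trials`` epochs (prestimulus, stimulus,
    poststimulus), separated by noise-only padding; oscillatory components
    run continuously with per-phase amplitude envelopes. Identical config
    (including seed) yields bit-identical output.

    Stream order from the master seed: 0 = noise, 1 = withdrawal
    latencies, 2 = oscillator phases.
    """
    fs = config.sampling_rate
    noise_rng, latency_rng, phase_rng = (
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(config.seed).spawn(3)
    )

    latencies = latency_rng.uniform(*config.withdrawal_latency_range, config.n_trials)

    # Build the event timeline: pad | prestim | stim | poststim | pad | ...
    onsets, withdrawals = [], []
    cursor = config.inter_trial_pad
    for latency in latencies:
        onset = cursor + config.prestim_duration
        onsets.append(onset)
        withdrawals.append(onset + latency)
        cursor = onset + latency + config.poststim_duration + config.inter_trial_pad
    n_samples = int(round(cursor * fs))

    t = np.arange(n_samples) / fs
    trace = colored_noise(
        n_samples, config.noise_exponent, noise_rng, std=config.noise_scale
    )

    ramp_samples = int(round(config.ramp_duration * fs))
    for schedule in config.band_schedules:
        env = np.zeros(n_samples)
        for onset, wd in zip(onsets, withdrawals):
            i_pre = int(round((onset - config.prestim_duration) * fs))
            i_on = int(round(onset * fs))
            i_wd = int(round(wd * fs))
            i_end = min(int(round((wd + config.poststim_duration) * fs)), n_samples)
            env[i_pre:i_on] = schedule.prestim_amplitude
            env[i_on:i_wd] = schedule.stim_amplitude
            env[i_wd:i_end] = schedule.prestim_amplitude
        env = _smooth_envelope(env, ramp_samples)
        phase = phase_rng.uniform(0, 2 * np.pi)
        trace = trace + env * np.sin(2 * np.pi * schedule.center_freq * t + phase)

    recording = LfpRecording(samples=trace, sampling_rate=fs, channel_id="rACC")
    rows = []
    for i, (onset, wd) in enumerate(zip(onsets, withdrawals)):
        trial = f"trial_{i:03d}"
        rows.append((trial, "stimulus_onset", onset))
        rows.append((trial, "paw_withdrawal", wd))
    events = EventTable(
        pd.DataFrame(rows, columns=["trial_id", "event", "time_s"]),
        duration_s=recording.duration_s,
    )
    return recording, events


@dataclass(frozen=True)
class BehaviorDesign:
    """Group x timepoint design for the behavioral tables.

    ``pwt_sd`` is the reading-to-reading noise sd in grams; a subject
    intercept with sd ``pwt_sd / 2`` adds within-subject correlation, and
    both vanish when ``pwt_sd`` is 0 so that the generated readings equal
    the group means exactly.
    """

    groups: tuple[str, ...] = GROUPS
    n_per_group: int = 7
    timepoints: tuple[str, ...] = PWT_TIMEPOINTS
    group_mean_pwt: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PWT_MEANS)
    )
    pwt_sd: float = 4.0
    n_readings: int = 5
    cpa_days: tuple[str, ...] = CPA_DAYS
    cpa_mean_occupancy: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_CPA_PAIN_MEANS.items()}
    )
    occupancy_sd: float = 80.0
    active_total_mean: float = 1700.0  # time spent in either compartment, s
    active_total_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        for group in self.groups:
            means = self.group_mean_pwt.get(group)
            if means is None or len(means) != len(self.timepoints):
                raise ConfigurationError(
                    f"group_mean_pwt: group {group!r} needs one mean per timepoint"
                )
            if any(m < 0 or m > 50 for m in means):
                raise ConfigurationError(
                    f"group_mean_pwt: {group!r} means must lie in [0, 50] grams"
                )
            occ = self.cpa_mean_occupancy.get(group)
            if occ is None or set(self.cpa_days) - set(occ):
                raise ConfigurationError(
                    f"cpa_mean_occupancy: group {group!r} needs one mean per day"
                )
            if any(v < 0 or v > 1800 for v in occ.values()):
                raise ConfigurationError(
                    "cpa_mean_occupancy: means must lie within the 1800 s session"
                )
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group: must be >= 1")
        if self.pwt_sd < 0 or self.occupancy_sd < 0:
            raise ConfigurationError("pwt_sd / occupancy_sd: must be >= 0")


def generate_behavior(design: BehaviorDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate PWT readings and CPA occupancies for the whole cohort.

    Returns long-format tables:

    * PWT: (subject, group, timepoint, trial_index, grams) with
      ``n_readings`` rows per subject x timepoint, clipped to [0, 50] g.
    * CPA: (subject, group, day, compartment, occupancy_s) with both
      compartments per subject x day; the two occupancies are carved out
      of a total active time so they never exceed the 1800 s session.

    Stream order from the master seed: 0 = PWT, 1 = CPA.
    """
    pwt_rng, cpa_rng = (
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(design.seed).spawn(2)
    )

    pwt_rows = []
    for group in design.groups:
        means = design.group_mean_pwt[group]
        for j in range(design.n_per_group):
            subject = f"{group}_{j:02d}"
            intercept = pwt_rng.normal(0.0, design.pwt_sd / 2.0)
            for timepoint, mean in zip(design.timepoints, means):
                readings = mean + intercept + pwt_rng.normal(
                    0.0, design.pwt_sd, design.n_readings
                )
                for k, grams in enumerate(np.clip(readings, 0.0, 50.0), start=1):
                    pwt_rows.append((subject, group, timepoint, k, float(grams)))
    pwt = pd.DataFrame(
        pwt_rows, columns=["subject", "group", "timepoint", "trial_index", "grams"]
    )

    cpa_rows = []
    for group in design.groups:
        occ_means = design.cpa_mean_occupancy[group]
        for j in range(design.n_per_group):
            subject = f"{group}_{j:02d}"
            for day in design.cpa_days:
                active = float(np.clip(
                    cpa_rng.normal(design.active_total_mean, design.active_total_sd),
                    0.0, 1800.0,
                ))
                pain = float(np.clip(
                    occ_means[day] + cpa_rng.normal(0.0, design.occupancy_sd),
                    0.0, active,
                ))
                cpa_rows.append((subject, group, day, "pain_paired", pain))
                cpa_rows.append((subject, group, day, "non_pain_paired", active - pain))
    cpa = pd.DataFrame(
        cpa_rows, columns=["subject", "group", "day", "compartment", "occupancy_s"]
    )
    return pwt, cpa
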