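"""Readers and writers for the on-disk formats used throughout the pipeline.

Continuous signals are stored as little-endian float32 flat binary
(``lfp.bin``) with a JSON sidecar (``lfp.json``) declaring sampling rate,
length, dtype, units and channel id; a CSV dialect is accepted as a
secondary store. Event and behavioral tables are plain UTF-8 CSV with a
header row. All readers validate strictly and reject malformed input
rather than repairing it.

Conventions fixed once and used everywhere: times are seconds as floats
anchored at recording start, sample indexing is 0-based, and segments are
half-open intervals ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LfpRecording",
    "EventTable",
    "SchemaError",
    "IntegrityError",
    "ValidationError",
    "read_lfp",
    "write_lfp",
    "read_events",
    "read_pwt",
    "read_cpa",
    "validate_events",
    "validate_pwt",
    "validate_cpa",
    "CPA_SESSION_LENGTH_S",
]

#: Length of one free-movement CPA session in seconds (30 min).
CPA_SESSION_LENGTH_S = 1800.0

EVENT_LABELS = ("stimulus_onset", "paw_withdrawal")
CPA_COMPARTMENTS = ("pain_paired", "non_pain_paired")


class SchemaError(ValueError):
    """A file is missing required metadata or columns."""


class IntegrityError(ValueError):
    """Sidecar metadata and payload disagree."""


class ValidationError(ValueError):
    """Table contents violate a domain invariant."""


@dataclass(frozen=True)
class LfpRecording:
    """A uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples
        1-D float array, finite everywhere.
    sampling_rate
        Samples per second; must be positive.
    channel_id
        Opaque channel label.
    units
        Opaque amplitude unit label (the acquisition chain's gain is not
        modeled, so units are carried as metadata only).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_id: str = "ch0"
    units: str = "au"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValidationError("samples must be a 1-D vector")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples contain NaN or Inf")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class EventTable:
    """Per-trial stimulus-onset / paw-withdrawal timestamps.

    Backed by a DataFrame with columns ``trial_id`` (str), ``event``
    (``stimulus_onset`` or ``paw_withdrawal``) and ``time_s`` (seconds from
    recording start). Per trial there is exactly one onset, at most one
    withdrawal, and the withdrawal follows the onset strictly.
    """

    frame: pd.DataFrame
    duration_s: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frame", validate_events(self.frame, duration_s=self.duration_s)
        )

    @property
    def trial_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["trial_id"]))

    def onset(self, trial_id: str) -> float:
        return float(
            self.frame.query(
                "trial_id == @trial_id and event == 'stimulus_onset'"
            )["time_s"].iloc[0]
        )

    def withdrawal(self, trial_id: str) -> float | None:
        rows = self.frame.query(
            "trial_id == @trial_id and event == 'paw_withdrawal'"
        )
        return float(rows["time_s"].iloc[0]) if len(rows) else None


def validate_events(
    frame: pd.DataFrame, duration_s: float | None = None
) -> pd.DataFrame:
    """Validate an event table; returns a normalized copy or raises."""
    required = {"trial_id", "event", "time_s"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"event table missing columns: {sorted(missing)}")
    out = frame.copy()
    out["trial_id"] = out["trial_id"].astype(str)
    out["time_s"] = out["time_s"].astype(float)
    bad = set(out["event"]) - set(EVENT_LABELS)
    if bad:
        raise SchemaError(f"unknown event labels: {sorted(bad)}")
    if duration_s is not None and (out["time_s"] > duration_s).any():
        over = out.loc[out["time_s"] > duration_s, "trial_id"].iloc[0]
        raise ValidationError(
            f"trial {over!r}: event time beyond recording duration {duration_s} s"
        )
    if (out["time_s"] < 0).any():
        raise ValidationError("negative event times")
    for trial_id, grp in out.groupby("trial_id", sort=False):
        n_on = int((grp["event"] == "stimulus_onset").sum())
        n_off = int((grp["event"] == "paw_withdrawal").sum())
        if n_on != 1:
            raise ValidationError(
                f"trial {trial_id!r}: expected exactly one stimulus_onset, found {n_on}"
            )
        if n_off > 1:
            raise ValidationError(
                f"trial {trial_id!r}: more than one paw_withdrawal"
            )
        if n_off == 1:
            onset = grp.loc[grp["event"] == "stimulus_onset", "time_s"].iloc[0]
            wd = grp.loc[grp["event"] == "paw_withdrawal", "time_s"].iloc[0]
            if wd <= onset:
                raise ValidationError(
                    f"trial {trial_id!r}: paw_withdrawal at {wd} s not after "
                    f"stimulus_onset at {onset} s"
                )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# continuous-signal store

def write_lfp(recording: LfpRecording, path: str | Path, dialect: str = "binary") -> Path:
    """Write a recording to ``path`` (extension-less stem or explicit file).

    ``binary`` writes ``<stem>.bin`` (little-endian float32) plus
    ``<stem>.json`` sidecar; ``csv`` writes a two-column CSV with the
    sidecar metadata embedded as a JSON sidecar as well.
    """
    path = Path(path)
    stem = path.with_suffix("") if path.suffix in {".bin", ".csv", ".json"} else path
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "n_samples": recording.n_samples,
        "dtype": "float32" if dialect == "binary" else "csv",
        "units": recording.units,
        "channel_id": recording.channel_id,
    }
    if dialect == "binary":
        payload = stem.with_suffix(".bin")
        recording.samples.astype("<f4").tofile(payload)
    elif dialect == "csv":
        payload = stem.with_suffix(".csv")
        pd.DataFrame(
            {"sample_index": np.arange(recording.n_samples), "value": recording.samples}
        ).to_csv(payload, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return payload


def read_lfp(path: str | Path) -> LfpRecording:
    """Read a recording written by :func:`write_lfp` (either dialect)."""
    path = Path(path)
    stem = path.with_suffix("")
    sidecar_path = stem.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("sampling_rate", "n_samples"):
        if key not in sidecar:
            raise SchemaError(f"sidecar missing required field {key!r}")
    if stem.with_suffix(".bin").exists():
        samples = np.fromfile(stem.with_suffix(".bin"), dtype="<f4").astype(np.float64)
    elif stem.with_suffix(".csv").exists():
        samples = pd.read_csv(stem.with_suffix(".csv"))["value"].to_numpy(float)
    else:
        raise SchemaError(f"no payload (.bin or .csv) next to {sidecar_path}")
    if samples.size != int(sidecar["n_samples"]):
        raise IntegrityError(
            f"sidecar declares {sidecar['n_samples']} samples, payload has {samples.size}"
        )
    return LfpRecording(
        samples=samples,
        sampling_rate=float(sidecar["sampling_rate"]),
        channel_id=str(sidecar.get("channel_id", "ch0")),
        units=str(sidecar.get("units", "au")),
    )


# ---------------------------------------------------------------------------
# tabular readers

def read_events(path: str | Path, duration_s: float | None = None) -> EventTable:
    return EventTable(pd.read_csv(path), duration_s=duration_s)


def validate_pwt(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format paw-withdrawal-threshold table."""
    required = {"subject", "group", "timepoint", "trial_index", "grams"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"pwt table missing columns: {sorted(missing)}")
    out = frame.copy()
    out["grams"] = out["grams"].astype(float)
    if ((out["grams"] < 0) | (out["grams"] > 50)).any():
        row = out[(out["grams"] < 0) | (out["grams"] > 50)].iloc[0]
        raise ValidationError(
            f"subject {row['subject']!r} at {row['timepoint']!r}: "
            f"grams {row['grams']} outside the instrument range [0, 50]"
        )
    dup = out.duplicated(subset=["subject", "timepoint", "trial_index"])
    if dup.any():
        row = out[dup].iloc[0]
        raise ValidationError(
            f"subject {row['subject']!r} at {row['timepoint']!r}: "
            f"duplicate trial_index {row['trial_index']}"
        )
    return out.reset_index(drop=True)


def validate_cpa(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format CPA compartment-occupancy table."""
    required = {"subject", "group", "day", "compartment", "occupancy_s"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"cpa table missing columns: {sorted(missing)}")
    out = frame.copy()
    out["occupancy_s"] = out["occupancy_s"].astype(float)
    bad = set(out["compartment"]) - set(CPA_COMPARTMENTS)
    if bad:
        raise SchemaError(f"unknown compartments: {sorted(bad)}")
    if (out["occupancy_s"] < 0).any():
        raise ValidationError("negative occupancy time")
    if (out["occupancy_s"] > CPA_SESSION_LENGTH_S).any():
        row = out[out["occupancy_s"] > CPA_SESSION_LENGTH_S].iloc[0]
        raise ValidationError(
            f"subject {row['subject']!r} day {row['day']!r}: occupancy "
            f"{row['occupancy_s']} s exceeds the {CPA_SESSION_LENGTH_S:.0f} s session"
        )
    sums = out.groupby(["subject", "day"])["occupancy_s"].sum()
    if (sums > CPA_SESSION_LENGTH_S).any():
        subject, day = sums[sums > CPA_SESSION_LENGTH_S].index[0]
        raise ValidationError(
            f"subject {subject!r} day {day!r}: compartment occupancies sum past "
            f"the {CPA_SESSION_LENGTH_S:.0f} s session"
        )
    return out.reset_index(drop=True)


def read_pwt(path: str | Path) -> pd.DataFrame:
    return validate_pwt(pd.read_csv(path))


def read_cpa(path: str | Path) -> pd.DataFrame:
    return validate_cpa(pd.read_csv(path))
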