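"""End-to-end orchestration: simulate -> filter -> psd -> bandpower ->
behavior -> stats, as one reproducible, manifest-carrying run.

Every stage writes its outputs to the run directory in the open formats
defined in :mod:`painmem.io`, so each stage is independently re-invocable
on the previous stage's files. A single master seed is split into one
stream per simulated object (rule: ``SeedSequence(seed).generate_state(2)
% 2**31`` gives the session seed then the behavior seed), which makes a
run bit-reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import BANDS, BandDefinition, band_phase_means, segment_phases
from .behavior import cpa_scores_table, pwt_scores_table
from .io import EventTable, read_events, read_lfp, write_lfp
from .preprocess import FilterSpec, bandpass
from .spectral import SpectralConfig, spectrogram
from .stats import bonferroni, rm_anova_mixed, rm_anova_oneway, significance_report
from .synthetic import (
    BandSchedule,
    BehaviorDesign,
    SessionConfig,
    generate_behavior,
    generate_session,
)

__all__ = ["RunConfig", "run_all", "band_contrast_report"]

logger = logging.getLogger(__name__)

BROADBAND = BandDefinition("broadband", 2.0, 45.0, closed_high=True)


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable configuration for one pipeline run."""

    seed: int = 0
    alpha: float = 0.05
    prestim_s: float = 5.0
    poststim_s: float = 5.0
    session: SessionConfig = field(default_factory=SessionConfig)
    behavior: BehaviorDesign = field(default_factory=BehaviorDesign)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return {
            "seed": self.seed,
            "alpha": self.alpha,
            "prestim_s": self.prestim_s,
            "poststim_s": self.poststim_s,
            "session": plain(self.session),
            "behavior": plain(self.behavior),
            "filter": plain(self.filter_spec),
            "spectral": plain(self.spectral),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        session_kwargs = dict(data.get("session", {}))
        schedules = session_kwargs.pop("band_schedules", None)
        if schedules is not None:
            session_kwargs["band_schedules"] = tuple(
                BandSchedule(**s) if isinstance(s, dict) else s for s in schedules
            )
        for key in ("withdrawal_latency_range",):
            if key in session_kwargs and isinstance(session_kwargs[key], list):
                session_kwargs[key] = tuple(session_kwargs[key])
        behavior_kwargs = dict(data.get("behavior", {}))
        for key in ("groups", "timepoints", "cpa_days"):
            if key in behavior_kwargs:
                behavior_kwargs[key] = tuple(behavior_kwargs[key])
        if "group_mean_pwt" in behavior_kwargs:
            behavior_kwargs["group_mean_pwt"] = {
                g: tuple(v) for g, v in behavior_kwargs["group_mean_pwt"].items()
            }
        spectral_kwargs = dict(data.get("spectral", {}))
        if "freq_range_hz" in spectral_kwargs:
            spectral_kwargs["freq_range_hz"] = tuple(spectral_kwargs["freq_range_hz"])
        return cls(
            seed=int(data.get("seed", 0)),
            alpha=float(data.get("alpha", 0.05)),
            prestim_s=float(data.get("prestim_s", 5.0)),
            poststim_s=float(data.get("poststim_s", 5.0)),
            session=SessionConfig(**session_kwargs),
            behavior=BehaviorDesign(**behavior_kwargs),
            filter_spec=FilterSpec(**data.get("filter", {})),
            spectral=SpectralConfig(**spectral_kwargs),
        )

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def derived_seeds(self) -> tuple[int, int]:
        state = np.random.SeedSequence(self.seed).generate_state(2)
        return int(state[0] % 2**31), int(state[1] % 2**31)


def band_contrast_report(
    band_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Prestimulus-vs-stimulus one-way rm ANOVA per band, over trials.

    Trials play the role of repeated subjects within a session. All
    contrasts performed (broadband plus the canonical bands) form one
    Bonferroni family, so the report's family-wise false-flag rate stays
    at the nominal alpha.
    """
    rows = []
    sub = band_table[band_table["phase"].isin(["prestimulus", "stimulus"])]
    band_names = [b for b in sub["band"].unique()]
    for band in band_names:
        one = sub[sub["band"] == band].rename(
            columns={"trial_id": "subject", "phase": "condition",
                     "mean_psd_db": "value"}
        )
        res = rm_anova_oneway(one)
        stim = one[one["condition"] == "stimulus"]["value"].mean()
        pre = one[one["condition"] == "prestimulus"]["value"].mean()
        rows.append((band, stim - pre, res.F, res.df_num, res.df_den, res.p))
    report = pd.DataFrame(
        rows, columns=["band", "stim_minus_prestim_db", "F", "df_num", "df_den", "p"]
    )
    report["p_adjusted"] = bonferroni(report["p"].to_numpy(), len(report))
    report["significant"] = report["p_adjusted"] < alpha
    return report


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the whole pipeline into ``outdir``; returns paths and tables.

    Deterministic given the config (byte-identical CSVs across runs); the
    manifest records the config, its hash, derived seeds and per-stage row
    counts, and re-loads to an identical config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    session_seed, behavior_seed = config.derived_seeds()
    counts: dict[str, int] = {}

    # simulate
    session_cfg = dataclasses.replace(config.session, seed=session_seed)
    behavior_design = dataclasses.replace(config.behavior, seed=behavior_seed)
    recording, events = generate_session(session_cfg)
    pwt, cpa = generate_behavior(behavior_design)
    write_lfp(recording, outdir / "lfp")
    events.frame.to_csv(outdir / "events.csv", index=False)
    pwt.to_csv(outdir / "pwt.csv", index=False)
    cpa.to_csv(outdir / "cpa.csv", index=False)
    counts["events"] = len(events.frame)
    counts["pwt"] = len(pwt)
    counts["cpa"] = len(cpa)

    # filter
    recording = read_lfp(outdir / "lfp.bin")
    filtered = bandpass(recording, config.filter_spec)
    write_lfp(filtered, outdir / "lfp_filtered")

    # psd
    spec = spectrogram(filtered, config.spectral)
    long = pd.DataFrame(
        {
            "time_s": np.repeat(spec.time_bins_s, spec.freq_bins_hz.size),
            "freq_hz": np.tile(spec.freq_bins_hz, spec.time_bins_s.size),
            "power_db": spec.power_db.ravel(),
        }
    )
    long.to_csv(outdir / "spectrogram.csv", index=False)
    counts["spectrogram"] = len(long)

    # bandpower
    events = read_events(outdir / "events.csv", duration_s=filtered.duration_s)
    phases = segment_phases(
        events, prestim_s=config.prestim_s, poststim_s=config.poststim_s,
        recording_duration_s=filtered.duration_s,
    )
    band_table = band_phase_means(
        spec, phases, bands=BANDS + (BROADBAND,),
        recording=filtered, config=config.spectral,
    )
    band_table.to_csv(outdir / "band_phase.csv", index=False)
    counts["band_phase"] = len(band_table)
    n_trials_kept = band_table["trial_id"].nunique()
    counts["trials_excluded"] = len(events.trial_ids) - n_trials_kept

    # behavior
    pwt_scores = pwt_scores_table(pwt)
    cpa_scores = cpa_scores_table(cpa)
    pwt_scores.to_csv(outdir / "pwt_scores.csv", index=False)
    cpa_scores.to_csv(outdir / "cpa_scores.csv", index=False)

    # stats
    band_report = band_contrast_report(band_table, alpha=config.alpha)
    pwt_anova = rm_anova_mixed(
        pwt_scores.rename(columns={"pwt_grams": "value"}), value="value"
    )
    cpa_anova = rm_anova_mixed(
        cpa_scores.rename(columns={"cpa_score_s": "value", "day": "timepoint"}),
        value="value",
    )
    pwt_report = significance_report(pwt_anova, alpha=config.alpha)
    cpa_report = significance_report(cpa_anova, alpha=config.alpha)
    anova_out = pd.concat(
        [
            pwt_report.assign(analysis="pwt"),
            cpa_report.assign(analysis="cpa"),
        ],
        ignore_index=True,
    )
    band_report.to_csv(outdir / "band_contrasts.csv", index=False)
    anova_out.to_csv(outdir / "anova_results.csv", index=False)
    _write_text_report(outdir / "report.txt", config, band_report, pwt_report,
                       cpa_report)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "derived_seeds": {"session": session_seed, "behavior": behavior_seed},
        "row_counts": counts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return {
        "outdir": outdir,
        "band_table": band_table,
        "band_report": band_report,
        "pwt_anova": pwt_anova,
        "cpa_anova": cpa_anova,
        "manifest": manifest,
    }


def _write_text_report(path, config, band_report, pwt_report, cpa_report) -> None:
    lines = [
        "painmem run report",
        f"alpha = {config.alpha}",
        "",
        "Prestimulus vs stimulus mean-PSD contrasts (one-way rm ANOVA over trials)",
        band_report.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        "",
        "PWT two-way mixed rm ANOVA",
        pwt_report.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        "",
        "CPA-score two-way mixed rm ANOVA",
        cpa_report.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        "",
    ]
    Path(path).write_text("\n".join(lines))
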