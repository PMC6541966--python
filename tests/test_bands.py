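import numpy as np
import pandas as pd
import pytest

from painmem import (
    BANDS,
    LfpRecording,
    SpectralConfig,
    band_phase_means,
    compartment_phase_means,
    segment_phases,
    spectrogram,
)
from painmem.bands import PhaseWindows
from painmem.io import EventTable
from painmem.pipeline import BROADBAND
from painmem.spectral import SpectrogramResult


def make_events(rows):
    return EventTable(pd.DataFrame(rows, columns=["trial_id", "event", "time_s"]))


class TestBandTiling:
    def test_bands_tile_2_to_45_without_gaps_or_overlaps(self):
        edges = [(b.low_hz, b.high_hz) for b in BANDS]
        assert edges[0][0] == 2.0 and edges[-1][1] == 45.0
        for (lo, hi), (lo2, _) in zip(edges, edges[1:]):
            assert hi == lo2
        freqs = np.linspace(2.0, 45.0, 500)
        membership = np.sum([b.contains(freqs) for b in BANDS], axis=0)
        assert np.all(membership == 1)


class TestSegmentPhases:
    def test_phase_windows_follow_convention(self):
        events = make_events(
            [("t1", "stimulus_onset", 100.0), ("t1", "paw_withdrawal", 104.2)]
        )
        windows = segment_phases(events).intervals("t1")
        assert windows["prestimulus"] == (95.0, 100.0)
        assert windows["stimulus"] == (100.0, 104.2)
        assert windows["poststimulus"] == (104.2, 109.2)

    def test_onset_too_close_to_start_excludes_trial(self, caplog):
        events = make_events([("t1", "stimulus_onset", 3.0)])
        with caplog.at_level("WARNING"):
            windows = segment_phases(events)
        assert windows.frame.empty
        assert "t1" in caplog.text

    def test_missing_withdrawal_truncates_at_ramp_end_and_flags(self):
        events = make_events([("t1", "stimulus_onset", 30.0)])
        frame = segment_phases(events).frame
        stim = frame[frame["phase"] == "stimulus"].iloc[0]
        assert stim["end_s"] == pytest.approx(50.0)
        assert bool(stim["flagged"])


class TestBandPhaseMeans:
    def _theta_flat_spectrogram(self):
        freqs = np.arange(3, 47) * (1000 / 1024)
        theta = (freqs >= 4) & (freqs < 9)
        power = np.where(theta, 0.0, -40.0)[None, :].repeat(30, axis=0)
        times = 0.512 + np.arange(30) * 0.512
        return SpectrogramResult(time_bins_s=times, freq_bins_hz=freqs,
                                 power_db=power)

    def test_constant_field_recovers_band_levels(self):
        spec = self._theta_flat_spectrogram()
        phases = PhaseWindows(pd.DataFrame(
            [("t1", "prestimulus", 0.0, 15.0, False)],
            columns=["trial_id", "phase", "start_s", "end_s", "flagged"],
        ))
        table = band_phase_means(spec, phases)
        by_band = table.set_index("band")["mean_psd_db"]
        assert by_band["theta"] == pytest.approx(0.0)
        assert by_band["alpha"] == pytest.approx(-40.0)

    def test_matches_brute_force_double_loop(self, random_spectrogram):
        spec = random_spectrogram
        phases = PhaseWindows(pd.DataFrame(
            [("t1", "prestimulus", 0.5, 4.0, False),
             ("t1", "stimulus", 4.0, 8.0, False)],
            columns=["trial_id", "phase", "start_s", "end_s", "flagged"],
        ))
        table = band_phase_means(spec, phases)
        for rec in phases.frame.itertuples():
            for band in BANDS:
                acc, count = 0.0, 0
                for i, t in enumerate(spec.time_bins_s):
                    if not (rec.start_s <= t < rec.end_s):
                        continue
                    for j, f in enumerate(spec.freq_bins_hz):
                        upper = f <= band.high_hz if band.closed_high else f < band.high_hz
                        if band.low_hz <= f and upper:
                            acc += spec.power_db[i, j]
                            count += 1
                expected = acc / count
                got = table[
                    (table["phase"] == rec.phase) & (table["band"] == band.name)
                ]["mean_psd_db"].iloc[0]
                assert got == pytest.approx(expected, abs=1e-12)

    def test_band_partition_identity(self, random_spectrogram):
        # bin-count-weighted combination of band means == broadband mean
        spec = random_spectrogram
        phases = PhaseWindows(pd.DataFrame(
            [("t1", "stimulus", 0.0, 100.0, False)],
            columns=["trial_id", "phase", "start_s", "end_s", "flagged"],
        ))
        table = band_phase_means(spec, phases, bands=BANDS + (BROADBAND,))
        by_band = table.set_index("band")["mean_psd_db"]
        weights = np.array([b.contains(spec.freq_bins_hz).sum() for b in BANDS])
        combo = np.average([by_band[b.name] for b in BANDS], weights=weights)
        assert combo == pytest.approx(by_band["broadband"], abs=1e-9)

    def test_short_stimulus_phase_uses_single_window_fallback(self, caplog):
        fs = 1000.0
        rng = np.random.default_rng(0)
        recording = LfpRecording(samples=rng.standard_normal(int(20 * fs)),
                                 sampling_rate=fs)
        config = SpectralConfig()
        spec = spectrogram(recording, config)
        phases = PhaseWindows(pd.DataFrame(
            [("t1", "stimulus", 10.0, 10.4, False),    # 400 samples -> 256 window
             ("t2", "stimulus", 12.0, 12.2, False)],   # 200 samples -> dropped
            columns=["trial_id", "phase", "start_s", "end_s", "flagged"],
        ))
        with caplog.at_level("WARNING"):
            table = band_phase_means(spec, phases, recording=recording,
                                     config=config)
        assert set(table["trial_id"]) == {"t1"}
        assert "t2" in caplog.text


class TestCompartmentMeans:
    def test_full_recording_interval_equals_whole_band_means(self, random_spectrogram):
        spec = random_spectrogram
        whole = compartment_phase_means(spec, [(0.0, 1e6)], labels=["all"])
        phases = PhaseWindows(pd.DataFrame(
            [("all", "occupancy", 0.0, 1e6, False)],
            columns=["trial_id", "phase", "start_s", "end_s", "flagged"],
        ))
        direct = band_phase_means(spec, phases)
        merged = whole.merge(direct, on=["trial_id", "band"], suffixes=("_a", "_b"))
        assert np.allclose(merged["mean_psd_db_a"], merged["mean_psd_db_b"])

    def test_equal_intervals_on_constant_field_match_single_interval(self):
        freqs = np.arange(3, 47) * (1000 / 1024)
        spec = SpectrogramResult(
            time_bins_s=0.5 + np.arange(40) * 0.5,
            freq_bins_hz=freqs,
            power_db=np.full((40, freqs.size), -12.5),
        )
        double = compartment_phase_means(spec, [(0.0, 5.0), (10.0, 15.0)])
        single = compartment_phase_means(spec, [(0.0, 5.0)])
        for band in single["band"]:
            vals = double[double["band"] == band]["mean_psd_db"]
            assert np.allclose(vals, -12.5)
            assert np.allclose(
                single[single["band"] == band]["mean_psd_db"], vals.iloc[0]
            )
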