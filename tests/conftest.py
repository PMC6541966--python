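import numpy as np
import pandas as pd
import pytest

from painmem import (
    LfpRecording,
    SessionConfig,
    SpectralConfig,
    SpectrogramResult,
    bandpass,
    band_phase_means,
    generate_session,
    segment_phases,
    spectrogram,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_session():
    """A quick 5-trial session with the default theta-suppression schedule."""
    config = SessionConfig(n_trials=5, seed=7)
    recording, events = generate_session(config)
    return config, recording, events


@pytest.fixture
def random_spectrogram(rng):
    times = np.arange(20) * 0.512 + 0.512
    freqs = np.arange(3, 47) * (1000 / 1024)
    power = rng.normal(-20.0, 5.0, size=(times.size, freqs.size))
    return SpectrogramResult(time_bins_s=times, freq_bins_hz=freqs, power_db=power)


def theta_contrast(config: SessionConfig) -> pd.Series:
    """Run the full spectral chain; mean stim - prestim dB per band."""
    recording, events = generate_session(config)
    filtered = bandpass(recording)
    spec_cfg = SpectralConfig()
    spec = spectrogram(filtered, spec_cfg)
    phases = segment_phases(events, recording_duration_s=recording.duration_s)
    table = band_phase_means(
        spec, phases, recording=filtered, config=spec_cfg
    )
    piv = table.groupby(["band", "phase"])["mean_psd_db"].mean().unstack()
    return piv["stimulus"] - piv["prestimulus"]


def sine_recording(freq_hz, duration_s=10.0, fs=1000.0, amplitude=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return LfpRecording(samples=amplitude * np.sin(2 * np.pi * freq_hz * t),
                       sampling_rate=fs)
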