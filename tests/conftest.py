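import numpy as np
import pytest

from bulbarkit.sigio import TimeSeries
from bulbarkit.synthgen import COHORT_BASELINES, AudioSpec, make_recording, make_speech_audio


@pytest.fixture(scope="session")
def baseline_params():
    return {k: v[0] for k, v in COHORT_BASELINES.items()}


@pytest.fixture(scope="session")
def one_recording(baseline_params):
    """One control-like synthetic recording used across integration tests."""
    rng = np.random.default_rng(2024)
    return make_recording(
        "P00", "control", "M", baseline_params, 1, 3.4, rng, 160.0
    )


@pytest.fixture(scope="session")
def sawtooth_150(scope="session"):
    """2-s voiced sawtooth at 150 Hz with mild syllable-rate AM."""
    spec = AudioSpec(
        duration_s=2.0, f0_contour=[(0.0, 2.0, 150.0)],
        theta_am_depth=0.3, seed=7,
    )
    audio, seg, (t, f0) = make_speech_audio(spec)
    return audio, seg, f0


def tone(freq, duration_s, fs, amp=1.0, phase=0.0):
    t = np.arange(int(round(duration_s * fs))) / fs
    return TimeSeries(amp * np.cos(2 * np.pi * freq * t + phase), fs)
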