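"""Envelope extraction, theta modulation depth, n:m PSI, cochlear filterbank."""

import numpy as np
import pytest

from bulbarkit.rhythm import (
    CRITICAL_BANDS,
    ENVELOPE_FS,
    cochlear_band_edges,
    cochlear_critical_envelopes,
    critical_band_of,
    envelope_100hz,
    nm_psi,
    rhythm_feature_block,
    theta_mod_depth,
)
from bulbarkit.sigio import SEMG_CHANNELS, TimeSeries
from bulbarkit.speechseg import Segmentation
from bulbarkit.synthgen import AudioSpec, make_speech_audio


def env_ts(x):
    return TimeSeries(np.asarray(x, dtype=float), ENVELOPE_FS)


def env_tone(freq, dur, dc=1.0, amp=1.0):
    t = np.arange(int(dur * ENVELOPE_FS)) / ENVELOPE_FS
    return env_ts(dc + amp * np.cos(2 * np.pi * freq * t))


class TestEnvelope:
    def test_am_tone_envelope_recovered(self):
        fs = 22050.0
        t = np.arange(int(4 * fs)) / fs
        x = (1 + 0.5 * np.cos(2 * np.pi * 5 * t)) * np.cos(2 * np.pi * 1000 * t)
        env = envelope_100hz(TimeSeries(x, fs))
        expected = 1 + 0.5 * np.cos(2 * np.pi * 5 * np.arange(env.n) / 100.0)
        core = slice(20, -20)
        err = np.max(np.abs(env.samples[core] - expected[core]))
        assert err < 0.05 * expected.max()

    def test_constant_tone_constant_envelope(self):
        fs = 22050.0
        t = np.arange(int(3 * fs)) / fs
        env = envelope_100hz(TimeSeries(np.cos(2 * np.pi * 500 * t), fs))
        core = env.samples[20:-20]
        assert np.std(core) < 0.02 * np.mean(core)

    def test_pause_excision_shortens_envelope(self):
        fs = 2000.0
        ts = TimeSeries(np.random.default_rng(0).standard_normal(int(4 * fs)), fs)
        seg = Segmentation(
            [("speech", 0.0, 1.5), ("pause", 1.5, 2.5), ("speech", 2.5, 4.0)], 4.0)
        full = envelope_100hz(ts)
        cut = envelope_100hz(ts, seg)
        assert full.n - cut.n == pytest.approx(100, abs=2)


class TestModDepth:
    def test_pure_theta_tone(self):
        assert theta_mod_depth(env_tone(5.0, 10.0)) > 0.95

    def test_delta_tone_low_depth(self):
        assert theta_mod_depth(env_tone(1.5, 10.0)) < 0.1

    def test_two_equal_tones_half_depth(self):
        t = np.arange(int(20 * ENVELOPE_FS)) / ENVELOPE_FS
        env = env_ts(2 + np.cos(2 * np.pi * 5 * t) + np.cos(2 * np.pi * 20 * t))
        assert theta_mod_depth(env) == pytest.approx(0.5, abs=0.05)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            theta_mod_depth(env_tone(5.0, 1.0))


class TestPSI:
    def test_perfect_two_to_one_locking(self):
        t = np.arange(int(30 * ENVELOPE_FS)) / ENVELOPE_FS
        env = env_ts(
            2 + np.cos(2 * np.pi * 1.5 * t) + np.cos(2 * np.pi * 3.0 * t))
        psi = nm_psi(env_ts(env.samples), (0.9, 2.5), (2.5, 12.0), 2, 1)
        assert psi > 0.95

    def test_independent_narrowband_null(self):
        from scipy import signal
        psis = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(100 * ENVELOPE_FS)
            lo = signal.sosfiltfilt(
                signal.butter(4, [0.9, 2.5], "bandpass", fs=ENVELOPE_FS, output="sos"),
                rng.standard_normal(n))
            hi = signal.sosfiltfilt(
                signal.butter(4, [2.5, 12.0], "bandpass", fs=ENVELOPE_FS, output="sos"),
                rng.standard_normal(n))
            psis.append(nm_psi(env_ts(5 + lo + hi), (0.9, 2.5), (2.5, 12.0), 2, 1))
        assert np.mean(psis) < 0.1

    def test_amplitude_invariance(self):
        t = np.arange(int(30 * ENVELOPE_FS)) / ENVELOPE_FS
        base = 2 + np.cos(2 * np.pi * 1.5 * t + 0.3) + np.cos(2 * np.pi * 3.0 * t)
        p1 = nm_psi(env_ts(base), (0.9, 2.5), (2.5, 12.0), 2, 1)
        p2 = nm_psi(env_ts(10 * base), (0.9, 2.5), (2.5, 12.0), 2, 1)
        assert p1 == pytest.approx(p2, abs=1e-6)

    def test_self_one_to_one_is_unity(self):
        t = np.arange(int(30 * ENVELOPE_FS)) / ENVELOPE_FS
        env = env_ts(1 + 0.5 * np.cos(2 * np.pi * 5 * t))
        assert nm_psi(env, (2.5, 12.0), (2.5, 12.0), 1, 1) == pytest.approx(1.0)

    def test_null_psi_decays_with_length(self):
        from scipy import signal
        def null_psi(dur, seed):
            rng = np.random.default_rng(seed)
            n = int(dur * ENVELOPE_FS)
            lo = signal.sosfiltfilt(
                signal.butter(4, [0.9, 2.5], "bandpass", fs=ENVELOPE_FS, output="sos"),
                rng.standard_normal(n))
            hi = signal.sosfiltfilt(
                signal.butter(4, [2.5, 12.0], "bandpass", fs=ENVELOPE_FS, output="sos"),
                rng.standard_normal(n))
            return nm_psi(env_ts(5 + lo + hi), (0.9, 2.5), (2.5, 12.0), 2, 1)

        short = np.mean([null_psi(25.0, s) for s in range(8)])
        long = np.mean([null_psi(400.0, s) for s in range(8)])
        assert long < short

    def test_degenerate_band_raises(self):
        with pytest.raises(ValueError):
            nm_psi(env_ts(np.ones(3000)), (0.9, 2.5), (2.5, 12.0), 2, 1)


class TestCochlearBank:
    def test_partition_of_centers(self):
        edges = cochlear_band_edges()
        assert edges.size == 29
        for lo, hi in zip(edges[:-1], edges[1:]):
            center = np.sqrt(lo * hi)
            bands = [name for name, blo, bhi in CRITICAL_BANDS
                     if blo <= center < bhi]
            assert len(bands) <= 1
            if 800 <= center < 1000 or 8000 <= center < 10000:
                assert critical_band_of(center) is None

    def test_pure_tone_lands_in_its_band(self):
        fs = 22050.0
        t = np.arange(int(3 * fs)) / fs
        audio = TimeSeries(np.sin(2 * np.pi * 200 * t), fs)
        envs = cochlear_critical_envelopes(audio)
        power = {name: np.mean(e.samples ** 2) for name, e in envs.items()}
        assert all(power["100_300"] > 5 * power[b]
                   for b in power if b != "100_300")

    def test_white_noise_fills_all_bands(self):
        fs = 22050.0
        rng = np.random.default_rng(2)
        audio = TimeSeries(rng.standard_normal(int(3 * fs)), fs)
        envs = cochlear_critical_envelopes(audio)
        assert len(envs) == 4
        assert all(np.mean(e.samples ** 2) > 0 for e in envs.values())


class TestFeatureBlock:
    def test_counts_and_names(self, one_recording):
        from bulbarkit.speechseg import segment_speech_pauses
        from bulbarkit.sigio import preprocess_semg, rectify
        seg = segment_speech_pauses(
            one_recording.audio, speaking_rate_wpm=160.0)
        semg_envs = {
            ch: envelope_100hz(rectify(preprocess_semg(one_recording.semg[ch])), seg)
            for ch in SEMG_CHANNELS
        }
        cb = cochlear_critical_envelopes(one_recording.audio, seg)
        feats = rhythm_feature_block(semg_envs, cb)
        assert len(feats) == 21
        assert all(0.0 <= v <= 1.0 for v in feats.values())
        assert sum(k.startswith("hbenvlp_") for k in feats) == 12

    def test_strong_theta_am_gives_high_acoustic_depth(self):
        spec = AudioSpec(
            duration_s=4.0, f0_contour=[(0, 4.0, 150.0)],
            theta_am_rate=5.0, theta_am_depth=0.8, seed=6)
        audio, seg, _ = make_speech_audio(spec)
        envs = cochlear_critical_envelopes(audio, seg)
        depths = [theta_mod_depth(envs[name]) for name, _, _ in CRITICAL_BANDS]
        assert all(d > 0.5 for d in depths)
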