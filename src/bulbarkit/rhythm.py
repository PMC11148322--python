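"""Multiscale envelope rhythm metrics.

Speech and jaw-muscle activity are rhythmically organized at three nested
timescales: delta (0.9-2.5 Hz, prosodic stress), theta (2.5-12 Hz,
syllables), and beta/gamma (12-40 Hz, sub-syllabic segments). After pause
excision, each source signal is reduced to a 100-Hz Hilbert amplitude
envelope; from the envelope we compute

* **theta modulation depth** — the fraction of envelope spectral power in
  the theta band (2048-point FFT, Hamming window, DC excluded), a metric of
  syllable rhythm strength; and
* **n:m phase synchronization indices (PSI)** — the modulus of the
  time-averaged phasor of the generalized phase difference
  ``n*phi_slow - m*phi_fast`` between band-limited envelope components,
  with 2:1 for delta-theta (syllable alignment within prosodic units) and
  3:1 for theta-beta/gamma (sub-syllabic alignment within syllables).

Acoustic envelopes are taken per critical band: the waveform is split into
28 narrow bands spaced evenly on an auditory (ERB-rate) scale from 100 to
10,000 Hz, narrowband Hilbert envelopes are averaged within 100-300,
300-800, 1,000-3,000, and 3,000-8,000 Hz (vocal pitch, F1, F2, consonant
noise); the 800-1,000 and 8,000-10,000 Hz gaps belong to no critical band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .sigio import SEMG_CHANNELS, TimeSeries
from .speechseg import Segmentation, excise_pauses

ENVELOPE_FS = 100.0


@dataclass
class TimescaleBands:
    delta: tuple = (0.9, 2.5)
    theta: tuple = (2.5, 12.0)
    beta_gamma: tuple = (12.0, 40.0)


#: Critical bands: (Table-name suffix, lo_Hz, hi_Hz)
CRITICAL_BANDS = (
    ("100_300", 100.0, 300.0),
    ("300_800", 300.0, 800.0),
    ("1000_3000", 1000.0, 3000.0),
    ("3000_8000", 3000.0, 8000.0),
)

N_COCHLEAR_BANDS = 28
COCHLEAR_LO_HZ = 100.0
COCHLEAR_HI_HZ = 10000.0


@dataclass
class RhythmParams:
    nfft: int = 2048
    bands: TimescaleBands = field(default_factory=TimescaleBands)
    min_envelope_s: float = 1.0
    #: minimum record length for PSI, in cycles of the slower band's center
    psi_min_cycles: float = 3.0
    #: how narrowband envelopes are merged into critical bands
    combine: str = "mean"  # or "sum"


def envelope_100hz(
    ts: TimeSeries,
    segmentation: Segmentation | None = None,
    params: RhythmParams | None = None,
) -> TimeSeries:
    """Hilbert amplitude envelope, anti-aliased and resampled to 100 Hz.

    If a segmentation is given, pauses are excised (speech events
    concatenated) before the analytic signal is taken.
    """
    params = params or RhythmParams()
    if segmentation is not None:
        ts = excise_pauses(ts, segmentation)
    env = np.abs(signal.hilbert(ts.samples))
    frac = Fraction(int(round(ENVELOPE_FS)), int(round(ts.fs))).limit_denominator()
    out = signal.resample_poly(env, frac.numerator, frac.denominator)
    if out.size < params.min_envelope_s * ENVELOPE_FS:
        raise ValueError("envelope shorter than 1 s after pause excision")
    return TimeSeries(out, ENVELOPE_FS, label=ts.label)


def theta_mod_depth(envelope: TimeSeries, params: RhythmParams | None = None) -> float:
    """Theta-band fraction of the demeaned envelope's spectral power."""
    params = params or RhythmParams()
    x = envelope.samples - envelope.samples.mean()
    if envelope.duration_s < 2.0:
        raise ValueError("envelope must be at least 2 s for modulation depth")
    win = signal.get_window("hamming", x.size)
    spec = np.abs(np.fft.rfft(x * win, max(params.nfft, x.size))) ** 2
    freqs = np.fft.rfftfreq(max(params.nfft, x.size), d=1.0 / envelope.fs)
    total = spec[freqs > 0].sum()
    if total <= 0:
        raise ValueError("zero total envelope power")
    lo, hi = params.bands.theta
    band = spec[(freqs >= lo) & (freqs < hi)].sum()
    return float(band / total)


def _band_component(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x - x.mean())


def nm_psi(
    envelope: TimeSeries,
    band_slow: tuple,
    band_fast: tuple,
    n: int,
    m: int,
    params: RhythmParams | None = None,
) -> float:
    """n:m phase synchronization between two timescale components.

    Both bands are isolated with 4th-order zero-lag Butterworth filters;
    instantaneous phases come from the analytic signal; PSI is the modulus
    of the time-averaged phasor of ``n*phi_slow - m*phi_fast``. Amplitude-
    blind by construction: 0 = no locking, 1 = perfect locking.
    """
    params = params or RhythmParams()
    fc = 0.5 * (band_slow[0] + band_slow[1])
    if envelope.duration_s < params.psi_min_cycles / fc:
        raise ValueError("envelope too short for the slower timescale band")
    c1 = _band_component(envelope.samples, envelope.fs, *band_slow)
    c2 = _band_component(envelope.samples, envelope.fs, *band_fast)
    for c in (c1, c2):
        if np.std(c) < 1e-12 * max(np.std(envelope.samples), 1e-300):
            raise ValueError("degenerate (constant) band component")
    p1 = np.angle(signal.hilbert(c1))
    p2 = np.angle(signal.hilbert(c2))
    return float(np.abs(np.mean(np.exp(1j * (n * p1 - m * p2)))))


def psi_pair_features(envelope: TimeSeries, params: RhythmParams | None = None):
    """(delta-theta PSI at 2:1, theta-beta/gamma PSI at 3:1)."""
    params = params or RhythmParams()
    b = params.bands
    return (
        nm_psi(envelope, b.delta, b.theta, 2, 1, params),
        nm_psi(envelope, b.theta, b.beta_gamma, 3, 1, params),
    )


# ---------------------------------------------------------------------------
# Cochlear filterbank
# ---------------------------------------------------------------------------

def _erb_rate(f_hz):
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f_hz, dtype=float))


def _inv_erb_rate(e):
    return (10.0 ** (np.asarray(e, dtype=float) / 21.4) - 1.0) / 0.00437


def cochlear_band_edges(
    n_bands: int = N_COCHLEAR_BANDS,
    lo_hz: float = COCHLEAR_LO_HZ,
    hi_hz: float = COCHLEAR_HI_HZ,
) -> np.ndarray:
    """n_bands+1 edges equally spaced on the ERB-rate (cochlear-map) scale."""
    return _inv_erb_rate(np.linspace(_erb_rate(lo_hz), _erb_rate(hi_hz), n_bands + 1))


def critical_band_of(center_hz: float):
    """Critical band containing a narrowband center, or None (spectral gap)."""
    for name, lo, hi in CRITICAL_BANDS:
        if lo <= center_hz < hi:
            return name
    return None


def cochlear_critical_envelopes(
    audio: TimeSeries,
    segmentation: Segmentation | None = None,
    params: RhythmParams | None = None,
) -> dict:
    """Four critical-band envelopes at 100 Hz from the 28-band filterbank.

    Returns ``{band_suffix: TimeSeries}``. Each narrowband signal is a
    4th-order zero-lag Butterworth slice of the pause-excised waveform; its
    Hilbert envelope is resampled to 100 Hz, and critical-band envelopes are
    the mean (or sum, per config) of member narrowband envelopes whose
    centers fall inside the critical band.
    """
    params = params or RhythmParams()
    if segmentation is not None:
        audio = excise_pauses(audio, segmentation)
    edges = cochlear_band_edges()
    members: dict[str, list[np.ndarray]] = {name: [] for name, _, _ in CRITICAL_BANDS}
    for lo, hi in zip(edges[:-1], edges[1:]):
        center = math.sqrt(lo * hi)
        cb = critical_band_of(center)
        if cb is None:
            continue
        narrow = _band_component(audio.samples, audio.fs, lo, min(hi, audio.fs / 2 * 0.999))
        env = np.abs(signal.hilbert(narrow))
        frac = Fraction(int(round(ENVELOPE_FS)), int(round(audio.fs))).limit_denominator()
        members[cb].append(signal.resample_poly(env, frac.numerator, frac.denominator))
    out = {}
    for name, envs in members.items():
        if not envs:
            raise RuntimeError(f"no filterbank member in critical band {name}")
        stack = np.vstack(envs)
        combined = stack.sum(axis=0) if params.combine == "sum" else stack.mean(axis=0)
        out[name] = TimeSeries(combined, ENVELOPE_FS, label=f"hbenvlp_{name}")
    return out


# ---------------------------------------------------------------------------
# Feature block
# ---------------------------------------------------------------------------

def rhythm_feature_block(
    semg_envelopes: dict, critical_envelopes: dict,
    params: RhythmParams | None = None,
) -> dict:
    """9 sEMG + 12 acoustic rhythm features, keyed by their table names."""
    params = params or RhythmParams()
    out = {}
    for ch in SEMG_CHANNELS:
        env = semg_envelopes[ch]
        out[f"mod_depth_theta_{ch}"] = theta_mod_depth(env, params)
        dt, tb = psi_pair_features(env, params)
        out[f"PSI_delta_theta_{ch}"] = dt
        out[f"PSI_theta_beta.gamma_{ch}"] = tb
    for name, _, _ in CRITICAL_BANDS:
        env = critical_envelopes[name]
        out[f"hbenvlp_mod_depth_theta_{name}"] = theta_mod_depth(env, params)
        dt, tb = psi_pair_features(env, params)
        out[f"hbenvlp_PSI_delta_theta_{name}"] = dt
        out[f"hbenvlp_PSI_theta_beta.gamma_{name}"] = tb
    return out
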