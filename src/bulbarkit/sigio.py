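"""Recording containers, file I/O, and the sEMG preprocessing chain.

Signals are carried as :class:`TimeSeries` (samples + sampling rate + label).
A :class:`MultimodalRecording` bundles one speech sample: a mono audio
waveform (nominally 22,050 Hz) synchronized with three surface-EMG channels
(nominally 2,000 Hz) from the right anterior temporalis (RTEMP), right
masseter (RMAS), and right anterior belly of digastric (RABD), plus the
participant metadata that downstream analysis needs (group, sex, speaking
rate in words/min).

The preprocessing chain applied to every sEMG channel is: 60 Hz notch
(power-line), 20 Hz high-pass (movement artifact), both zero-phase
(forward-backward), then DC removal. For coherence analysis the rectified
channels are reduced to a concatenation of stationary 1-s epochs centered on
activity bursts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

logger = logging.getLogger("bulbarkit")

#: Canonical sEMG channel labels (right temporalis, masseter, digastric).
SEMG_CHANNELS = ("RTEMP", "RMAS", "RABD")

AUDIO_FS = 22050.0
SEMG_FS = 2000.0


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal."""

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if samples.ndim != 1:
            raise ValueError("TimeSeries expects a 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"non-finite samples in series {self.label!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class MultimodalRecording:
    """One speech sample: synchronized audio + three sEMG channels."""

    audio: TimeSeries
    semg: dict  # label -> TimeSeries, keys == SEMG_CHANNELS
    participant_id: str
    group: str  # "control", "ALS+B", "ALS-B" (or plain "ALS")
    sex: str  # "M" | "F"
    speaking_rate_wpm: float
    sentence_id: int = 1

    def __post_init__(self):
        if set(self.semg) != set(SEMG_CHANNELS):
            raise ValueError(
                f"expected sEMG channels {SEMG_CHANNELS}, got {tuple(self.semg)}"
            )
        if self.speaking_rate_wpm <= 0:
            raise ValueError("speaking_rate_wpm must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")


@dataclass
class PreprocessConfig:
    """sEMG conditioning constants.

    The burst detector and stationarity proxy are implementation choices
    (robust envelope threshold; half-to-half RMS ratio), exposed here so they
    can be audited and varied.
    """

    notch_hz: float = 60.0
    notch_q: float = 30.0
    highpass_hz: float = 20.0
    highpass_order: int = 4
    # burst detection on the 100-ms moving-RMS envelope of the rectified
    # signal: Otsu split of the log-envelope into quiescent/active classes,
    # accepted only when the active-class geometric mean exceeds the
    # quiescent one by `burst_contrast_min` (no contrast -> no bursts)
    burst_rms_win_s: float = 0.100
    burst_contrast_min: float = 3.0
    burst_min_dur_s: float = 0.200
    epoch_len_s: float = 1.0
    # epochs whose first/second-half RMS ratio exceeds this are non-stationary
    stationarity_rms_ratio: float = 3.0


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_wav(path, ts: TimeSeries) -> None:
    """Write a mono waveform as 16-bit PCM WAV (values clipped to [-1, 1])."""
    x = np.clip(ts.samples, -1.0, 1.0)
    wavfile.write(str(path), int(round(ts.fs)), (x * 32767.0).astype(np.int16))


def read_wav(path) -> TimeSeries:
    fs, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError("expected mono WAV audio")
    if data.dtype == np.int16:
        x = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        x = data.astype(float) / 2147483647.0
    else:
        x = data.astype(float)
    return TimeSeries(x, float(fs), label="audio")


def write_semg(path, channels: dict, sep: str = "\t") -> None:
    """Write sEMG channels as delimited text with a header row."""
    fs = {ts.fs for ts in channels.values()}
    if len(fs) != 1:
        raise ValueError("sEMG channels must share one sampling rate")
    pd.DataFrame({k: ts.samples for k, ts in channels.items()}).to_csv(
        path, sep=sep, index=False, float_format="%.9g"
    )


def read_semg(path, fs: float = SEMG_FS, sep=None) -> dict:
    """Read delimited sEMG text; columns are mapped by header label."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in SEMG_CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"sEMG file missing channel column(s): {missing}")
    if df.shape[1] < 3:
        raise ValueError("sEMG file must have at least 3 numeric columns")
    return {
        c: TimeSeries(df[c].to_numpy(dtype=float), fs, label=c)
        for c in SEMG_CHANNELS
    }


def read_recording(
    audio_path,
    semg_path,
    metadata: dict,
    expected_audio_fs: float = AUDIO_FS,
    expected_semg_fs: float = SEMG_FS,
    fs_rtol: float = 0.001,
) -> MultimodalRecording:
    """Load one synchronized audio + sEMG sample from disk.

    ``metadata`` must provide participant_id, group, sex and
    speaking_rate_wpm (sentence_id optional). Sampling rates are validated
    against the expected values within ``fs_rtol`` relative tolerance.
    """
    audio = read_wav(audio_path)
    if expected_audio_fs and abs(audio.fs - expected_audio_fs) > fs_rtol * expected_audio_fs:
        raise ValueError(
            f"audio sampling rate {audio.fs} Hz does not match expected "
            f"{expected_audio_fs} Hz"
        )
    semg = read_semg(semg_path, fs=expected_semg_fs)
    return MultimodalRecording(
        audio=audio,
        semg=semg,
        participant_id=str(metadata["participant_id"]),
        group=str(metadata["group"]),
        sex=str(metadata["sex"]),
        speaking_rate_wpm=float(metadata["speaking_rate_wpm"]),
        sentence_id=int(metadata.get("sentence_id", 1)),
    )


# ---------------------------------------------------------------------------
# sEMG preprocessing
# ---------------------------------------------------------------------------

def preprocess_semg(ts: TimeSeries, config: PreprocessConfig | None = None) -> TimeSeries:
    """Notch (60 Hz), high-pass (20 Hz), zero-phase; then remove DC."""
    config = config or PreprocessConfig()
    b_n, a_n = signal.iirnotch(config.notch_hz, config.notch_q, fs=ts.fs)
    sos_hp = signal.butter(
        config.highpass_order, config.highpass_hz, btype="highpass", fs=ts.fs,
        output="sos",
    )
    # filtfilt needs some warm-up length; reject clearly-too-short input
    min_len = 3 * (config.highpass_order * 2 + 1) + 1
    if ts.n < max(min_len, 64):
        raise ValueError(f"series too short for filtering ({ts.n} samples)")
    x = signal.filtfilt(b_n, a_n, ts.samples)
    x = signal.sosfiltfilt(sos_hp, x)
    x = x - x.mean()
    return ts.with_samples(x)


def rectify(ts: TimeSeries) -> TimeSeries:
    """Full-wave rectification: elementwise absolute value."""
    return ts.with_samples(np.abs(ts.samples))


def _moving_rms(x: np.ndarray, win: int) -> np.ndarray:
    win = max(1, win)
    kernel = np.ones(win) / win
    ms = np.convolve(x * x, kernel, mode="same")
    return np.sqrt(np.maximum(ms, 0.0))


def _otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Otsu's between-class-variance threshold on a 1-D sample."""
    hist, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_total = cum_m[-1] / total
    w0 = cum_w / total
    w1 = 1.0 - w0
    mu0 = np.where(cum_w > 0, cum_m / np.maximum(cum_w, 1), 0.0)
    mu1 = np.where(cum_w < total, (cum_m[-1] - cum_m) / np.maximum(total - cum_w, 1), mean_total)
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(centers[np.argmax(between[:-1])])


def detect_bursts(rectified: TimeSeries, config: PreprocessConfig | None = None):
    """Find activity intervals on the smoothed rectified envelope.

    The envelope is split into quiescent/active classes with an Otsu
    threshold; the split only counts as activity when the active-class mean
    exceeds the quiescent-class mean by ``burst_contrast_min``, so a record
    with no amplitude contrast (pure baseline noise) yields no bursts.
    Intervals shorter than ``burst_min_dur_s`` are discarded. Returns a list
    of (onset_s, offset_s).
    """
    config = config or PreprocessConfig()
    env = _moving_rms(rectified.samples, int(round(config.burst_rms_win_s * rectified.fs)))
    # threshold in the log domain: EMG activity sits decades above the
    # instrument floor, while within-burst fluctuation is comparatively small
    log_env = np.log(np.maximum(env, 1e-12))
    log_thr = _otsu_threshold(log_env)
    lo, hi = log_env[log_env <= log_thr], log_env[log_env > log_thr]
    if lo.size == 0 or hi.size == 0:
        return []
    if np.exp(hi.mean() - lo.mean()) < config.burst_contrast_min:
        return []
    above = log_env > log_thr
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    stops = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(above.size)
    out = []
    for s, e in zip(starts, stops):
        if (e - s) / rectified.fs >= config.burst_min_dur_s:
            out.append((s / rectified.fs, e / rectified.fs))
    return out


def burst_epoch_concat(
    rectified: TimeSeries, config: PreprocessConfig | None = None
):
    """Concatenate stationary 1-s epochs centered on activity bursts.

    Short bursts contribute one centered epoch; bursts longer than the epoch
    length are tiled with non-overlapping epochs. Epochs are clipped into the
    record, deduplicated against overlap, and screened with a stationarity
    proxy (first/second-half RMS ratio). Returns (concatenated TimeSeries,
    list of epoch center times in seconds).
    """
    config = config or PreprocessConfig()
    if rectified.duration_s < config.epoch_len_s:
        raise ValueError("record shorter than one epoch")
    bursts = detect_bursts(rectified, config)
    if not bursts:
        raise RuntimeError("no supra-threshold activity")
    ep = int(round(config.epoch_len_s * rectified.fs))
    n = rectified.n
    starts: list[int] = []

    def try_place(start: int):
        start = int(min(max(start, 0), n - ep))
        for s in starts:
            if start < s + ep and s < start + ep:  # overlap: shift right
                start = s + ep
        if start + ep <= n and all(
            not (start < s + ep and s < start + ep) for s in starts
        ):
            starts.append(start)

    for on, off in bursts:
        dur = off - on
        if dur <= config.epoch_len_s:
            center = 0.5 * (on + off)
            try_place(int(round(center * rectified.fs)) - ep // 2)
        else:
            k = int(dur // config.epoch_len_s)
            for j in range(k):
                try_place(int(round((on + j * config.epoch_len_s) * rectified.fs)))
    starts.sort()

    kept, centers = [], []
    for s in starts:
        seg = rectified.samples[s:s + ep]
        r1 = np.sqrt(np.mean(seg[: ep // 2] ** 2))
        r2 = np.sqrt(np.mean(seg[ep // 2:] ** 2))
        lo, hi = sorted((r1, r2))
        if lo > 0 and hi / lo > config.stationarity_rms_ratio:
            continue
        kept.append(seg)
        centers.append((s + ep / 2) / rectified.fs)
    if not kept:
        raise RuntimeError("no stationary epochs around detected bursts")
    out = TimeSeries(np.concatenate(kept), rectified.fs, label=rectified.label)
    logger.debug("%s: %d burst epoch(s)", rectified.label or "semg", len(kept))
    return out, centers
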