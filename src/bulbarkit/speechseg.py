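"""Pause/speech segmentation and f0-based prosody features.

Segmentation follows the Speech Pause Analysis scheme: a short-window RMS
energy envelope is thresholded at a fraction (0.04) of the waveform's peak
absolute amplitude; sub-threshold runs at least as long as the minimum pause
duration (150 ms baseline) become pauses, and supra-threshold runs shorter
than the minimum speech duration (35 ms baseline) are absorbed into adjacent
pauses. Both duration thresholds scale with speaking rate relative to a
160-WPM baseline, so slower speakers are held to proportionally longer
minima.

Prosody comes from a normalized cross-correlation f0 tracker (20-ms analysis
window for male voices, 10-ms for female) summarized on the semitone scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sigio import TimeSeries


@dataclass
class SegmentationParams:
    """Speech-pause differentiation thresholds (baseline at 160 WPM)."""

    min_pause_s: float = 0.150
    min_speech_s: float = 0.035
    amp_threshold: float = 0.04  # fraction of peak |waveform|
    baseline_rate_wpm: float = 160.0
    envelope_win_s: float = 0.010
    #: scale thresholds by baseline/actual rate ("inverse") or actual/baseline
    scale_direction: str = "inverse"

    def __post_init__(self):
        if min(self.min_pause_s, self.min_speech_s, self.amp_threshold,
               self.baseline_rate_wpm, self.envelope_win_s) <= 0:
            raise ValueError("all segmentation parameters must be positive")

    def scaled(self, speaking_rate_wpm: float):
        if speaking_rate_wpm <= 0:
            raise ValueError("speaking_rate_wpm must be positive")
        if self.scale_direction == "inverse":
            r = self.baseline_rate_wpm / speaking_rate_wpm
        else:
            r = speaking_rate_wpm / self.baseline_rate_wpm
        return self.min_pause_s * r, self.min_speech_s * r


@dataclass
class Segmentation:
    """Ordered, contiguous pause/speech events tiling one sample."""

    events: list  # (kind, onset_s, offset_s)
    duration_s: float

    def __post_init__(self):
        prev = 0.0
        for kind, on, off in self.events:
            if kind not in ("pause", "speech"):
                raise ValueError(f"unknown event kind {kind!r}")
            if off <= on or abs(on - prev) > 1e-6:
                raise ValueError("events must be contiguous and forward-ordered")
            prev = off
        if self.events and abs(prev - self.duration_s) > 1e-6:
            raise ValueError("events must tile the full duration")

    def pauses(self):
        return [(on, off) for kind, on, off in self.events if kind == "pause"]

    def speech(self):
        return [(on, off) for kind, on, off in self.events if kind == "speech"]

    def to_label_file(self, path) -> None:
        with open(path, "w") as fh:
            for kind, on, off in self.events:
                fh.write(f"{on:.6f}\t{off:.6f}\t{kind}\n")


@dataclass
class F0Trace:
    times_s: np.ndarray
    f0_hz: np.ndarray
    voiced: np.ndarray
    window_s: float

    def voiced_f0(self) -> np.ndarray:
        return self.f0_hz[self.voiced]


def _rms_envelope(x: np.ndarray, fs: float, win_s: float) -> np.ndarray:
    win = max(1, int(round(win_s * fs)))
    kernel = np.ones(win) / win
    return np.sqrt(np.maximum(np.convolve(x * x, kernel, mode="same"), 0.0))


def _runs(mask: np.ndarray):
    """Contiguous runs of True as (start, stop) index pairs."""
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[~mask[edges]] + 1)
    stops = list(edges[mask[edges]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def segment_speech_pauses(
    audio: TimeSeries,
    params: SegmentationParams | None = None,
    speaking_rate_wpm: float = 160.0,
) -> Segmentation:
    """Differentiate pauses from speech events on the audio timeline."""
    params = params or SegmentationParams()
    if audio.n == 0:
        raise ValueError("empty audio")
    min_pause, min_speech = params.scaled(speaking_rate_wpm)
    env = _rms_envelope(audio.samples, audio.fs, params.envelope_win_s)
    peak = np.max(np.abs(audio.samples))
    thr = params.amp_threshold * peak
    supra = env >= thr if peak > 0 else np.zeros(audio.n, dtype=bool)
    dur = audio.duration_s
    if not supra.any():
        warnings.warn("all-silent audio: emitting a single pause event")
        return Segmentation([("pause", 0.0, dur)], dur)

    # candidate pauses: sub-threshold runs >= scaled minimum pause duration
    pause_idx = [
        (s, e) for s, e in _runs(~supra) if (e - s) / audio.fs >= min_pause
    ]
    # provisional speech = complement; absorb runs < scaled minimum speech
    # duration into the neighboring pause
    bounds = [0] + [i for se in pause_idx for i in se] + [audio.n]
    merged = []
    for j, (ps, pe) in enumerate(pause_idx):
        merged.append([ps, pe])
    # absorb short speech runs between consecutive pauses
    out = []
    for seg in merged:
        if out:
            gap = (seg[0] - out[-1][1]) / audio.fs
            if gap < min_speech:
                out[-1][1] = seg[1]
                continue
        out.append(seg)
    # leading/trailing short speech absorbed into first/last pause
    if out and out[0][0] / audio.fs < min_speech:
        out[0][0] = 0
    if out and (audio.n - out[-1][1]) / audio.fs < min_speech:
        out[-1][1] = audio.n

    events = []
    cursor = 0
    for ps, pe in out:
        if ps > cursor:
            events.append(("speech", cursor / audio.fs, ps / audio.fs))
        events.append(("pause", ps / audio.fs, pe / audio.fs))
        cursor = pe
    if cursor < audio.n:
        events.append(("speech", cursor / audio.fs, dur))
    else:
        # make final offset exact
        kind, on, _ = events[-1]
        events[-1] = (kind, on, dur)
    return Segmentation(events, dur)


def pause_features(seg: Segmentation):
    """Mean/SD of pause duration (s) and percentage of pause time.

    No pauses -> (0, 0, 0); a single pause has SD 0 by convention.
    """
    durs = np.array([off - on for on, off in seg.pauses()])
    if durs.size == 0:
        return {"MeanDur_intrapause": 0.0, "SdevDur_intrapause": 0.0,
                "pct_intrapause": 0.0}
    sd = float(np.std(durs, ddof=1)) if durs.size > 1 else 0.0
    return {
        "MeanDur_intrapause": float(durs.mean()),
        "SdevDur_intrapause": sd,
        "pct_intrapause": float(100.0 * durs.sum() / seg.duration_s),
    }


# ---------------------------------------------------------------------------
# f0 / prosody
# ---------------------------------------------------------------------------

@dataclass
class F0Params:
    window_s_male: float = 0.020
    window_s_female: float = 0.010
    hop_s: float = 0.010
    f0_range_male: tuple = (60.0, 300.0)
    f0_range_female: tuple = (100.0, 500.0)
    voicing_threshold: float = 0.5  # normalized correlation
    energy_floor: float = 0.01  # fraction of peak frame RMS


def extract_f0(audio: TimeSeries, sex: str, params: F0Params | None = None) -> F0Trace:
    """Track f0 with frame-wise normalized cross-correlation.

    Each frame's waveform is correlated with itself at candidate pitch lags;
    the peak (parabolically interpolated) gives f0, and frames whose peak
    correlation falls below the voicing threshold — or whose energy is
    negligible — are marked unvoiced.
    """
    params = params or F0Params()
    if sex not in ("M", "F"):
        raise ValueError("sex must be 'M' or 'F'")
    win_s = params.window_s_male if sex == "M" else params.window_s_female
    lo, hi = params.f0_range_male if sex == "M" else params.f0_range_female
    fs = audio.fs
    W = int(round(win_s * fs))
    lag_min = max(2, int(np.floor(fs / hi)))
    lag_max = int(np.ceil(fs / lo))
    frame_len = W + lag_max
    hop = max(1, int(round(params.hop_s * fs)))
    x = audio.samples
    if x.size < frame_len:
        raise ValueError("audio shorter than one analysis frame")

    starts = np.arange(0, x.size - frame_len + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, frame_len)[starts]
    F = frames.shape[0]

    # cross-correlation numerator via FFT: c[k] = sum_i a[i] * b[i+k]
    nfft = int(2 ** np.ceil(np.log2(frame_len + W)))
    A = np.fft.rfft(frames[:, :W], nfft, axis=1)
    B = np.fft.rfft(frames, nfft, axis=1)
    corr = np.fft.irfft(np.conj(A) * B, nfft, axis=1)[:, : lag_max + 1]

    e0 = np.einsum("ij,ij->i", frames[:, :W], frames[:, :W])
    csq = np.concatenate(
        [np.zeros((F, 1)), np.cumsum(frames * frames, axis=1)], axis=1
    )
    lags = np.arange(lag_min, lag_max + 1)
    ek = csq[:, lags + W] - csq[:, lags]  # (F, L)
    denom = np.sqrt(np.maximum(e0[:, None] * ek, 1e-300))
    ncc = corr[:, lag_min:] / denom

    # a periodic frame correlates equally at k*T; prefer the shortest-lag
    # local maximum within 95% of the global peak to avoid octave errors
    peak = ncc.max(axis=1)
    localmax = np.zeros_like(ncc, dtype=bool)
    localmax[:, 1:-1] = (ncc[:, 1:-1] >= ncc[:, :-2]) & (ncc[:, 1:-1] >= ncc[:, 2:])
    near = localmax & (ncc >= 0.95 * np.maximum(peak[:, None], 1e-300))
    has_near = near.any(axis=1)
    best = np.where(has_near, np.argmax(near, axis=1), np.argmax(ncc, axis=1))
    # parabolic interpolation of the lag peak
    lag_f = lags[best].astype(float)
    inner = (best > 0) & (best < ncc.shape[1] - 1)
    if inner.any():
        i = np.flatnonzero(inner)
        y0 = ncc[i, best[i] - 1]
        y1 = ncc[i, best[i]]
        y2 = ncc[i, best[i] + 1]
        denom2 = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom2) > 1e-12, 0.5 * (y0 - y2) / denom2, 0.0)
        lag_f[i] = lags[best[i]] + np.clip(shift, -1, 1)

    f0 = fs / lag_f
    frame_rms = np.sqrt(np.maximum(e0 / W, 0.0))
    voiced = (peak >= params.voicing_threshold) & (
        frame_rms >= params.energy_floor * max(frame_rms.max(), 1e-300)
    )
    f0 = np.where(voiced, f0, 0.0)
    times = (starts + W / 2) / fs
    if not voiced.any():
        raise ValueError("unvoiced sample: no voiced frame found")
    return F0Trace(times_s=times, f0_hz=f0, voiced=voiced, window_s=win_s)


SEMITONE_REF_HZ = 1.0


def prosody_features(trace: F0Trace, ref_hz: float = SEMITONE_REF_HZ):
    """Mean, SD, and IQR of the voiced f0 trace on the semitone scale.

    The semitone reference (1 Hz) only translates the mean; SD and IQR are
    reference-invariant. SD is the population SD over voiced frames.
    """
    f0 = trace.voiced_f0()
    if f0.size < 2:
        raise ValueError("need at least 2 voiced frames for prosody features")
    st = 12.0 * np.log2(f0 / ref_hz)
    q75, q25 = np.percentile(st, [75, 25])
    return {
        "meanF0.st": float(st.mean()),
        "sdevF0.st": float(st.std(ddof=0)),
        "iqrF0.st": float(q75 - q25),
    }


def excise_pauses(ts: TimeSeries, seg: Segmentation) -> TimeSeries:
    """Concatenate the speech events of ``ts`` (drop all pauses).

    Works for any sampling rate: event times are mapped to sample indices on
    ``ts``'s own clock, so the same segmentation drives both the audio and
    the sEMG channels.
    """
    parts = []
    for on, off in seg.speech():
        i0, i1 = int(round(on * ts.fs)), min(int(round(off * ts.fs)), ts.n)
        if i1 > i0:
            parts.append(ts.samples[i0:i1])
    if not parts:
        raise ValueError("segmentation leaves no speech samples")
    return ts.with_samples(np.concatenate(parts))
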