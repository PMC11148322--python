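"""Complexity via recurrence quantification analysis (RQA).

A signal's phase-space trajectory is reconstructed by delay embedding
(dimension ``m``, delay ``tau``) of the z-scored series; two embedded points
recur when their Euclidean distance is within ``eps`` times the maximal
pairwise distance. Determinism (DET) is the fraction of recurrence points
lying on diagonal line structures of length >= ``lmin`` — high for periodic
signals, low for structurally complex ones, hence inversely related to
signal complexity.

Two parameterizations are used: sEMG channels are analyzed in non-
overlapping 1-s segments with (m=30, tau=5, eps=0.1) and DET averaged over
segments; the acoustic signal is summarized by its first 13 mel-frequency
cepstral coefficient (MFCC) series, each analyzed with (m=3, tau=15,
eps=0.2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from scipy.spatial.distance import pdist, squareform

from .sigio import SEMG_CHANNELS, TimeSeries

SEMG_RQA = dict(m=30, tau=5, eps=0.1)
MFCC_RQA = dict(m=3, tau=15, eps=0.2)


@dataclass
class RQAParams:
    m: int = 3
    tau: int = 1
    eps: float = 0.1
    lmin: int = 2
    theiler: int = 1  # exclude |i-j| < theiler (1 = line of identity only)
    #: eps is a fraction of the maximal pairwise embedded distance
    eps_mode: str = "max_distance"  # or "sd"

    def __post_init__(self):
        if self.m < 1 or self.tau < 1 or self.eps <= 0 or self.lmin < 2:
            raise ValueError("invalid RQA parameters")


@dataclass
class RecurrencePlot:
    R: np.ndarray  # boolean, symmetric, LOI excluded
    params: RQAParams

    @property
    def n_points(self) -> int:
        return int(self.R.sum())


def delay_embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = x.size - (m - 1) * tau
    if n < 2:
        raise ValueError("series too short for this embedding")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def recurrence_plot(series: np.ndarray, params: RQAParams) -> RecurrencePlot:
    """Thresholded pairwise-distance matrix of the embedded z-scored series."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant series: z-score undefined")
    x = (x - x.mean()) / sd
    if x.size <= (params.m - 1) * params.tau + params.lmin:
        raise ValueError("series too short for recurrence analysis")
    X = delay_embed(x, params.m, params.tau)
    d = pdist(X)
    scale = d.max() if params.eps_mode == "max_distance" else X.std()
    if scale == 0:
        raise ValueError("degenerate embedding: all points identical")
    R = squareform(d <= params.eps * scale)
    if params.theiler > 1:
        n = R.shape[0]
        i, j = np.indices((n, n))
        R[np.abs(i - j) < params.theiler] = False
    # squareform already leaves the LOI (theiler = 1) off the plot
    return RecurrencePlot(R=R, params=params)


def determinism(rp: RecurrencePlot) -> float:
    """Fraction of recurrence points on diagonals of length >= lmin."""
    R = rp.R
    n = R.shape[0]
    total = int(R.sum())
    if total == 0:
        warnings.warn("recurrence plot has no recurrence points; DET := 0")
        return 0.0
    on_lines = 0
    lmin = rp.params.lmin
    for k in range(max(rp.params.theiler, 1), n):
        diag = np.ascontiguousarray(R.diagonal(k)).astype(np.int8)
        if diag.sum() == 0:
            continue
        # run lengths of consecutive ones
        padded = np.concatenate(([0], diag, [0]))
        d = np.diff(padded)
        run_starts = np.flatnonzero(d == 1)
        run_stops = np.flatnonzero(d == -1)
        lengths = run_stops - run_starts
        on_lines += int(lengths[lengths >= lmin].sum())
    return float(2 * on_lines / total)  # both triangles are symmetric


def det_of_series(series: np.ndarray, params: RQAParams) -> float:
    return determinism(recurrence_plot(series, params))


def semg_determinism_features(
    semg: dict,
    params: RQAParams | None = None,
    segment_s: float = 1.0,
    max_segments: int | None = None,
) -> dict:
    """Segment-averaged DET per sEMG channel.

    Each channel is cut into non-overlapping 1-s segments analyzed with the
    sEMG parameterization; DET is averaged over segments. ``max_segments``
    caps the number analyzed (evenly spread across the record) to bound
    runtime on long cohorts.
    """
    params = params or RQAParams(**SEMG_RQA)
    out = {}
    for ch in SEMG_CHANNELS:
        ts = semg[ch]
        seg_len = int(round(segment_s * ts.fs))
        k = ts.n // seg_len
        if k < 1:
            raise ValueError(f"channel {ch} shorter than one {segment_s}-s segment")
        idx = np.arange(k)
        if max_segments is not None and k > max_segments:
            idx = np.unique(np.linspace(0, k - 1, max_segments).round().astype(int))
        dets = [
            det_of_series(ts.samples[i * seg_len:(i + 1) * seg_len], params)
            for i in idx
        ]
        out[f"DET_{ch}"] = float(np.mean(dets))
    return out


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, nfft: int, fs: float, lo_hz=0.0, hi_hz=None):
    """Triangular mel filterbank over the one-sided spectrum bins."""
    hi_hz = hi_hz or fs / 2
    mels = np.linspace(_hz_to_mel(lo_hz), _hz_to_mel(hi_hz), n_filters + 2)
    bins = np.floor((nfft + 1) * _mel_to_hz(mels) / fs).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(n_filters):
        l, c, r = bins[i], bins[i + 1], bins[i + 2]
        if c > l:
            fb[i, l:c] = (np.arange(l, c) - l) / (c - l)
        if r > c:
            fb[i, c:r] = (r - np.arange(c, r)) / (r - c)
    return fb


def mfcc_matrix(
    audio: TimeSeries,
    n_mfcc: int = 13,
    frame_s: float = 0.025,
    hop_s: float = 0.010,
    n_filters: int = 26,
) -> np.ndarray:
    """First ``n_mfcc`` MFCCs (c1..c13; c0/energy excluded), rows = coefficients.

    Framing: 25-ms Hamming frames at a 10-ms hop; 26 triangular mel filters
    on the power spectrum; log energies; orthonormal DCT-II.
    """
    fs = audio.fs
    frame = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    x = audio.samples
    if x.size < frame:
        raise ValueError("audio shorter than one MFCC frame")
    starts = np.arange(0, x.size - frame + 1, hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, frame)[starts]
    win = np.hamming(frame)
    nfft = int(2 ** np.ceil(np.log2(frame)))
    power = np.abs(np.fft.rfft(frames * win, nfft, axis=1)) ** 2
    fb = mel_filterbank(n_filters, nfft, fs)
    logmel = np.log(np.maximum(power @ fb.T, 1e-12))
    cep = dct(logmel, type=2, norm="ortho", axis=1)
    return cep[:, 1:n_mfcc + 1].T  # (n_mfcc, n_frames)


def mfcc_determinism_features(
    audio: TimeSeries, params: RQAParams | None = None
) -> dict:
    """DET of each of the 13 MFCC coefficient series."""
    params = params or RQAParams(**MFCC_RQA)
    M = mfcc_matrix(audio)
    if M.shape[1] <= (params.m - 1) * params.tau + params.lmin:
        raise ValueError("too few MFCC frames for recurrence analysis")
    return {
        f"DET_mfcc{i + 1}": det_of_series(M[i], params) for i in range(M.shape[0])
    }
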