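"""Calibration-free amplitude features via visibility-graph density.

Recording gain and force-generation capacity confound raw amplitude, so
amplitude dynamics are summarized scale-invariantly: the signal is reduced
to a local-standard-deviation series over non-overlapping 50-ms blocks
(1,103 samples at 22,050 Hz for audio, 100 samples at 2,000 Hz for sEMG),
the series is converted to a natural visibility graph (two points connect
iff the straight line between them clears every intermediate point), and the
graph's edge density ``2m / (M(M-1))`` is the feature. Distinctive amplitude
peaks "see" far, so healthy, well-modulated signals have denser graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sigio import TimeSeries

AUDIO_BLOCK_LEN = 1103  # 22,050 Hz x 50 ms (as fixed upstream)
SEMG_BLOCK_LEN = 100    # 2,000 Hz x 50 ms


@dataclass
class LocalSDSeries:
    V: np.ndarray
    L: int
    fs: float


@dataclass
class VisibilityGraph:
    M: int
    edges: frozenset  # of (i, j) with i < j, 0-based

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        if self.M < 2:
            raise ValueError("density undefined for fewer than 2 vertices")
        return 2.0 * self.m / (self.M * (self.M - 1))


def local_sd_series(ts: TimeSeries, L: int) -> LocalSDSeries:
    """SD of each non-overlapping L-sample block (denominator L-1).

    The partial final block is dropped. Requires at least two full blocks.
    """
    if L < 2:
        raise ValueError("block length must be at least 2")
    M = ts.n // L
    if M < 2:
        raise ValueError(f"need >= 2 blocks of {L} samples, have {ts.n}")
    blocks = ts.samples[: M * L].reshape(M, L)
    V = blocks.std(axis=1, ddof=1)
    return LocalSDSeries(V=V, L=L, fs=ts.fs)


def visibility_graph(V: np.ndarray) -> VisibilityGraph:
    """Natural visibility graph of a series.

    Vertices x < y connect iff for every z strictly between them
    ``(V_y - V_z)/(y - z) > (V_y - V_x)/(y - x)`` — equivalently, the slope
    from x to y strictly exceeds the slope from x to every intermediate z.
    Adjacent vertices are connected vacuously; ties (collinear points) block
    visibility because the inequality is strict.
    """
    V = np.asarray(V, dtype=float)
    M = V.size
    if M < 2:
        raise ValueError("need at least 2 vertices")
    edges = set()
    for x in range(M - 1):
        max_slope = -np.inf
        for y in range(x + 1, M):
            s = (V[y] - V[x]) / (y - x)
            if y == x + 1 or s > max_slope:
                edges.add((x, y))
            if s > max_slope:
                max_slope = s
    return VisibilityGraph(M=M, edges=frozenset(edges))


def density_feature(ts: TimeSeries, L: int) -> float:
    """Visibility-graph density of the local-SD series of ``ts``."""
    return visibility_graph(local_sd_series(ts, L).V).density


def amplitude_features(semg: dict, audio: TimeSeries) -> dict:
    """density_RTEMP/RMAS/RABD (L=100) and density_audio (L=1,103)."""
    out = {
        f"density_{label}": density_feature(ts, SEMG_BLOCK_LEN)
        for label, ts in semg.items()
    }
    out["density_audio"] = density_feature(audio, AUDIO_BLOCK_LEN)
    return out
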