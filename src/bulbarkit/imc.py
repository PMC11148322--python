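"""Intermuscular coherence (IMC) and significance-gated band features.

Coherence between a pair of rectified, burst-epoched sEMG channels is the
magnitude-squared coherence ``|S_xy|^2 / (S_xx * S_yy)``, estimated with
Welch averaging over a 1,024-point Hamming window at 75% overlap and a
4,096-point FFT. Under the hypothesis of independent channels, the upper
95% confidence limit is ``S = 1 - 0.05**(1/(L_hat - 1))`` where ``L_hat`` is
the adjusted (variance-equivalent) number of averaged segments; band-mean
coherence values below S are zeroed because sub-significance coherence
carries no functional-connectivity information.

Nine features result: three muscle pairs (RTEMP-RMAS, RTEMP-RABD, RABD-RMAS)
by three bands — theta/alpha 4-12 Hz (slow subcortical drive), beta 12-30 Hz
(corticomuscular drive for submaximal tonic contraction), low gamma 30-60 Hz
(stronger tonic/phasic contraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .sigio import TimeSeries

#: Muscle pairs, in feature order.
MUSCLE_PAIRS = (("RTEMP", "RMAS"), ("RTEMP", "RABD"), ("RABD", "RMAS"))


@dataclass
class CoherenceParams:
    nfft: int = 4096
    win_len: int = 1024
    overlap: float = 0.75
    #: variance-equivalent independent-segment fraction for a Hamming window
    #: at 75% overlap (overlap-correction stand-in; see methods note)
    l_hat_factor: float = 0.52

    def __post_init__(self):
        if self.win_len > self.nfft:
            raise ValueError("win_len must not exceed nfft")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def step(self) -> int:
        return max(1, int(round(self.win_len * (1.0 - self.overlap))))

    def n_segments(self, n: int) -> int:
        if n < self.win_len:
            return 0
        return 1 + (n - self.win_len) // self.step


@dataclass
class BandDefinition:
    theta_alpha: tuple = (4.0, 12.0)
    beta: tuple = (12.0, 30.0)
    gamma: tuple = (30.0, 60.0)

    def items(self):
        return (("theta_alpha", self.theta_alpha), ("beta", self.beta),
                ("gamma", self.gamma))


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    coh: np.ndarray
    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    L_hat: float
    sig_level: float
    pair: tuple = ("x", "y")


def significance_threshold(L_hat: float) -> float:
    """Upper 95% confidence limit of coherence under independence."""
    if L_hat <= 1:
        raise ValueError("L_hat must exceed 1")
    return 1.0 - 0.05 ** (1.0 / (L_hat - 1.0))


def coherence_spectrum(
    x: TimeSeries, y: TimeSeries, params: CoherenceParams | None = None
) -> CoherenceSpectrum:
    """Welch cross/auto spectra and magnitude-squared coherence of a pair."""
    params = params or CoherenceParams()
    if x.n != y.n:
        raise ValueError("paired series must have equal length")
    if x.fs != y.fs:
        raise ValueError("paired series must share a sampling rate")
    if x.n < 2 * params.win_len:
        raise ValueError("need at least two analysis windows of signal")
    win = signal.get_window("hamming", params.win_len)
    noverlap = params.win_len - params.step
    kw = dict(fs=x.fs, window=win, nperseg=params.win_len, noverlap=noverlap,
              nfft=params.nfft, detrend="constant")
    f, sxy = signal.csd(x.samples, y.samples, **kw)
    _, sxx = signal.welch(x.samples, **kw)
    _, syy = signal.welch(y.samples, **kw)
    coh = np.abs(sxy) ** 2 / np.maximum(sxx * syy, 1e-300)
    coh = np.clip(coh, 0.0, 1.0)
    # variance-equivalent segment count: raw window count scaled down for
    # overlap redundancy
    K = params.n_segments(x.n)
    L_hat = max(K * params.l_hat_factor, 1.0 + 1e-6)
    return CoherenceSpectrum(
        freqs=f, coh=coh, sxx=sxx, syy=syy, sxy=sxy,
        L_hat=L_hat, sig_level=significance_threshold(L_hat),
        pair=(x.label or "x", y.label or "y"),
    )


def band_mean(spec: CoherenceSpectrum, lo: float, hi: float) -> float:
    """Mean coherence over bins with lo <= f < hi (half-open band)."""
    mask = (spec.freqs >= lo) & (spec.freqs < hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}) Hz outside the frequency grid")
    return float(spec.coh[mask].mean())


def band_coherence_features(
    specs: dict, bands: BandDefinition | None = None
) -> dict:
    """Significance-gated band-mean coherence for every pair and band.

    ``specs`` maps (label_a, label_b) to a CoherenceSpectrum. Band means
    below each spectrum's significance level are set to zero. Output keys
    are ``IMC_<a>_<b>_<band>``.
    """
    bands = bands or BandDefinition()
    out = {}
    for a, b in MUSCLE_PAIRS:
        spec = specs.get((a, b)) or specs.get((b, a))
        if spec is None:
            raise ValueError(f"missing coherence spectrum for pair {a}-{b}")
        for band_name, (lo, hi) in bands.items():
            v = band_mean(spec, lo, hi)
            out[f"IMC_{a}_{b}_{band_name}"] = v if v >= spec.sig_level else 0.0
    return out
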