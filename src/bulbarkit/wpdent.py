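"""Regularity via wavelet-packet Shannon entropy.

The signal is decomposed with a 3-level wavelet packet decomposition (full
binary tree, 8 terminal nodes in natural frequency order; Daubechies-4 with
periodized boundaries by default, so the transform is exactly orthogonal and
energy-conserving). For each node the Shannon entropy
``-sum_i s_i^2 ln s_i^2`` of its coefficients is computed and the 8 node
entropies are averaged into one regularity index per signal: the more
spread the signal's energy over time-frequency atoms, the higher the
entropy, the lower the regularity.

Coefficient normalization (default ``"global"``) divides by the *total*
signal energy, so a signal concentrated in few nodes scores low however its
energy is arranged within them; ``"node"`` normalizes each node to unit
energy independently, which makes node entropies length-comparable but
blind to the energy distribution across nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .sigio import TimeSeries


@dataclass
class WPDConfig:
    levels: int = 3
    wavelet: str = "db4"
    mode: str = "periodization"
    normalization: str = "global"  # or "node"

    @property
    def n_nodes(self) -> int:
        return 2 ** self.levels


def wpd_nodes(series: np.ndarray, config: WPDConfig | None = None) -> list:
    """Terminal-node coefficient vectors in natural (frequency) order."""
    config = config or WPDConfig()
    x = np.asarray(series, dtype=float)
    if x.size < config.n_nodes:
        raise ValueError("series shorter than the number of terminal nodes")
    wp = pywt.WaveletPacket(
        data=x, wavelet=config.wavelet, mode=config.mode,
        maxlevel=config.levels,
    )
    return [np.asarray(node.data, dtype=float)
            for node in wp.get_level(config.levels, order="freq")]


def parseval_error(series: np.ndarray, config: WPDConfig | None = None) -> float:
    """Relative deviation of summed node energy from input energy."""
    x = np.asarray(series, dtype=float)
    e_in = (x ** 2).sum()
    e_nodes = sum((c ** 2).sum() for c in wpd_nodes(x, config))
    return float(abs(e_nodes - e_in) / e_in)


@dataclass
class EntropyResult:
    node_entropies: np.ndarray  # 8 values
    node_energies: np.ndarray
    mean_entropy: float


def node_entropy(coeffs: np.ndarray, total_energy: float | None = None) -> float:
    """Shannon entropy of one node's energy-normalized coefficients.

    With ``total_energy`` omitted, the node itself is normalized to unit
    energy (so a single-coefficient node scores 0 and a uniform node of N
    coefficients scores ln N).
    """
    c2 = np.asarray(coeffs, dtype=float) ** 2
    e = c2.sum()
    if e == 0:
        warnings.warn("zero-energy node; entropy := 0")
        return 0.0
    p = c2 / (total_energy if total_energy else e)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def shannon_entropy_feature(
    series: np.ndarray, config: WPDConfig | None = None
) -> EntropyResult:
    """Mean Shannon entropy over the 8 wavelet-packet nodes."""
    config = config or WPDConfig()
    nodes = wpd_nodes(series, config)
    energies = np.array([(c ** 2).sum() for c in nodes])
    total = energies.sum()
    if total == 0:
        raise ValueError("zero-energy input")
    norm = total if config.normalization == "global" else None
    ents = np.array([node_entropy(c, norm) for c in nodes])
    return EntropyResult(
        node_entropies=ents, node_energies=energies,
        mean_entropy=float(ents.mean()),
    )


def regularity_features(semg: dict, audio: TimeSeries,
                        config: WPDConfig | None = None) -> dict:
    """ShanEn_RTEMP/RMAS/RABD and ShanEn_audio."""
    out = {
        f"ShanEn_{label}": shannon_entropy_feature(ts.samples, config).mean_entropy
        for label, ts in semg.items()
    }
    out["ShanEn_audio"] = shannon_entropy_feature(audio.samples, config).mean_entropy
    return out
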