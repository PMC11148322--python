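"""Synthetic multimodal recordings with known ground truth.

Real jaw-sEMG + speech corpora for this task are not publicly deposited, so
every downstream stage is exercised on signals whose generating parameters
are known exactly:

* speech-like audio: a band-limited sawtooth voice source (harmonics up to
  5 kHz) following a scheduled f0 contour, amplitude-modulated at a
  syllable-rate (theta) frequency, silenced over a scheduled set of pauses;
* sEMG triplets: burst-gated mixtures of a shared band-limited oscillatory
  drive and private noise, so the intermuscular coherence in the drive band
  is controlled by a single coupling parameter;
* cohorts: per-participant baseline parameters perturbed at the *signal*
  level for the clinical group, so group effects must survive the full
  extraction chain to be seen in the feature table;
* feature tables with a known latent-factor structure for testing the
  confirmatory factor analysis layer.

All generators are deterministic under a fixed seed and return their ground
truth alongside the signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .sigio import (
    SEMG_CHANNELS,
    MultimodalRecording,
    TimeSeries,
    write_semg,
    write_wav,
)
from .speechseg import Segmentation

VOICE_HARMONIC_LIMIT_HZ = 5000.0
EDGE_RAMP_S = 0.010  # raised-cosine on/offsets at voicing boundaries
BURST_RAMP_S = 0.050  # raised-cosine ramps of the sEMG burst envelope


@dataclass
class AudioSpec:
    """Recipe for one synthetic speech-like waveform."""

    duration_s: float
    fs: float = 22050.0
    #: voiced stretches: (start_s, end_s, f0_Hz)
    f0_contour: list = field(default_factory=list)
    #: scheduled silences: (onset_s, offset_s), non-overlapping, sorted
    pause_schedule: list = field(default_factory=list)
    theta_am_rate: float = 5.0
    theta_am_depth: float = 0.0
    noise_floor: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if not 0.0 <= self.theta_am_depth <= 1.0:
            raise ValueError("theta_am_depth must be in [0, 1]")
        prev = -np.inf
        for on, off in self.pause_schedule:
            if off <= on:
                raise ValueError("pause offset must exceed onset")
            if on < prev:
                raise ValueError("pauses must be sorted and non-overlapping")
            prev = off
        for start, end, f0 in self.f0_contour:
            if f0 <= 0 or end <= start:
                raise ValueError("invalid f0 contour segment")
            if self.fs <= 2 * min(VOICE_HARMONIC_LIMIT_HZ, f0):
                raise ValueError("fs too low for requested f0 content")


@dataclass
class SemgSpec:
    """Recipe for one synthetic three-channel sEMG recording."""

    duration_s: float
    fs: float = 2000.0
    #: activity bursts: (onset_s, offset_s)
    burst_schedule: list = field(default_factory=list)
    #: shared oscillatory drive bands: (lo_Hz, hi_Hz)
    drive_bands: list = field(default_factory=lambda: [(15.0, 30.0)])
    coupling: float = 0.5
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must be in [0, 1]")
        for lo, hi in self.drive_bands:
            if not (0.0 < lo < hi < self.fs / 2):
                raise ValueError("drive bands must lie within (0, fs/2)")


def _raised_cosine_gate(n: int, fs: float, intervals, ramp_s: float) -> np.ndarray:
    """0/1 gate over ``intervals`` with raised-cosine edges of ``ramp_s``."""
    gate = np.zeros(n)
    ramp = max(2, int(round(ramp_s * fs)))
    up = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
    for on, off in intervals:
        i0, i1 = int(round(on * fs)), int(round(off * fs))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 <= i0:
            continue
        seg = np.ones(i1 - i0)
        r = min(ramp, (i1 - i0) // 2)
        if r > 1:
            seg[:r] = up[:r]
            seg[-r:] = up[:r][::-1]
        gate[i0:i1] = np.maximum(gate[i0:i1], seg)
    return gate


def make_speech_audio(spec: AudioSpec):
    """Render a speech-like waveform from its spec.

    Returns ``(audio, segmentation, (f0_times, f0_hz))`` where the
    segmentation and f0 trace are the generating ground truth. Voiced
    stretches are band-limited sawtooths at the scheduled f0 (harmonics to
    5 kHz, 1/k roll-off), amplitude-modulated at ``theta_am_rate`` with the
    stated depth; scheduled pauses contain only the noise floor.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    f0_track = np.zeros(n)

    for start, end, f0 in spec.f0_contour:
        i0, i1 = int(round(start * spec.fs)), min(int(round(end * spec.fs)), n)
        if i1 <= i0:
            continue
        tt = t[i0:i1] - t[i0]
        seg = np.zeros(i1 - i0)
        k_max = int(VOICE_HARMONIC_LIMIT_HZ // f0)
        phase = rng.uniform(0, 2 * np.pi)
        for k in range(1, max(k_max, 1) + 1):
            seg += np.sin(2 * np.pi * k * f0 * tt + k * phase) / k
        x[i0:i1] = seg
        f0_track[i0:i1] = f0

    # syllable-rate amplitude modulation
    am = 1.0 + spec.theta_am_depth * np.sin(2 * np.pi * spec.theta_am_rate * t)
    x *= am / (1.0 + spec.theta_am_depth)

    # voicing gate with smooth edges; pauses override to silence
    voiced = [(s, e) for s, e, _ in spec.f0_contour]
    gate = _raised_cosine_gate(n, spec.fs, voiced, EDGE_RAMP_S) if voiced else np.ones(n)
    pause_gate = 1.0 - _raised_cosine_gate(n, spec.fs, spec.pause_schedule, EDGE_RAMP_S)
    x = x * gate * pause_gate
    for on, off in spec.pause_schedule:
        i0, i1 = int(round(on * spec.fs)), min(int(round(off * spec.fs)), n)
        f0_track[i0:i1] = 0.0

    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.7 / peak
    x += spec.noise_floor * rng.standard_normal(n)

    events = []
    cursor = 0.0
    for on, off in spec.pause_schedule:
        if on > cursor:
            events.append(("speech", cursor, on))
        events.append(("pause", on, off))
        cursor = off
    if cursor < spec.duration_s:
        events.append(("speech", cursor, spec.duration_s))
    seg = Segmentation(events=events, duration_s=spec.duration_s)

    audio = TimeSeries(x, spec.fs, label="audio")
    return audio, seg, (t, f0_track)


def _bandlimited_noise(rng, n, fs, bands):
    """Unit-variance noise confined to the union of ``bands``."""
    x = np.zeros(n)
    for lo, hi in bands:
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        x += signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def make_semg_triplet(spec: SemgSpec) -> dict:
    """Render three sEMG channels sharing a common oscillatory drive.

    Each channel is ``burst_envelope x (coupling*shared + (1-coupling)*private)
    + baseline noise``: with coupling 1 all channels carry an identical drive
    (coherence -> 1 in the drive band), with coupling 0 they are independent.
    Returns ``{label: TimeSeries}`` for RTEMP, RMAS, RABD.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    bursts = spec.burst_schedule or [(0.0, spec.duration_s)]
    envelope = _raised_cosine_gate(n, spec.fs, bursts, BURST_RAMP_S)
    shared = _bandlimited_noise(rng, n, spec.fs, spec.drive_bands)
    out = {}
    for label in SEMG_CHANNELS:
        private = _bandlimited_noise(rng, n, spec.fs, spec.drive_bands)
        drive = spec.coupling * shared + (1.0 - spec.coupling) * private
        x = envelope * drive + spec.noise_sd * rng.standard_normal(n)
        out[label] = TimeSeries(x, spec.fs, label=label)
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Baseline (control-group) signal parameters and their between-subject SDs.
#: The clinical group's means are shifted by effect_map[param] * sd.
COHORT_BASELINES = {
    "coupling": (0.60, 0.10),      # shared-drive mixing weight
    "am_depth": (0.60, 0.10),      # theta AM depth of the voice envelope
    "pause_dur": (0.30, 0.05),     # mean scheduled pause length, s
    "f0_var": (2.0, 0.5),          # within-sentence f0 excursion, semitones
}

#: Default large-effect perturbation: weaker coupling and syllable
#: modulation, longer pauses, flattened pitch — the direction the disease
#: moves each parameter.
DEFAULT_EFFECT_MAP = {
    "coupling": -2.0,
    "am_depth": -2.0,
    "pause_dur": +2.5,
    "f0_var": -1.5,
}

N_SENTENCES = 19  # sentences of the standard reading passage


def _clip01(x, lo=0.02, hi=0.98):
    return float(min(max(x, lo), hi))


def make_recording(
    participant_id: str,
    group: str,
    sex: str,
    params: dict,
    sentence_id: int,
    duration_s: float,
    rng: np.random.Generator,
    speaking_rate_wpm: float = 160.0,
) -> MultimodalRecording:
    """Render one sentence-level recording from participant parameters."""
    f0_base = 120.0 if sex == "M" else 210.0
    # alternate f0 excursions of +/- f0_var semitones around the base
    n_chunks = max(3, int(duration_s / 0.5))
    edges = np.linspace(0.0, duration_s, n_chunks + 1)
    contour = []
    for j in range(n_chunks):
        st = params["f0_var"] * rng.uniform(-1, 1)
        contour.append((edges[j], edges[j + 1], f0_base * 2 ** (st / 12.0)))
    # two pauses per sentence at roughly 40% and 75% of its length
    p = max(0.05, params["pause_dur"] * float(rng.uniform(0.8, 1.2)))
    q = max(0.05, params["pause_dur"] * float(rng.uniform(0.8, 1.2)))
    pauses = [
        (0.40 * duration_s, min(0.40 * duration_s + p, 0.70 * duration_s)),
        (0.75 * duration_s, min(0.75 * duration_s + q, 0.97 * duration_s)),
    ]
    aspec = AudioSpec(
        duration_s=duration_s,
        f0_contour=contour,
        pause_schedule=pauses,
        theta_am_rate=5.0,
        theta_am_depth=_clip01(params["am_depth"]),
        seed=int(rng.integers(2**31)),
    )
    audio, seg, _ = make_speech_audio(aspec)
    # sEMG bursts co-occur with the speech events
    bursts = [(on, off) for kind, on, off in seg.events if kind == "speech"]
    espec = SemgSpec(
        duration_s=duration_s,
        burst_schedule=bursts,
        drive_bands=[(15.0, 30.0)],
        coupling=_clip01(params["coupling"]),
        noise_sd=0.02,
        seed=int(rng.integers(2**31)),
    )
    semg = make_semg_triplet(espec)
    return MultimodalRecording(
        audio=audio,
        semg=semg,
        participant_id=participant_id,
        group=group,
        sex=sex,
        speaking_rate_wpm=speaking_rate_wpm,
        sentence_id=sentence_id,
    )


def make_cohort(
    n_per_group: int,
    effect_map: dict | None = None,
    seed: int = 0,
    n_sentences: int = N_SENTENCES,
    n_control: int | None = None,
    duration_range_s=(3.0, 3.8),
):
    """Generate a labeled cohort of sentence-level recordings.

    ``n_per_group`` clinical (ALS) participants — alternately labeled
    "ALS+B" (symptomatic, full effect) and "ALS-B" (prodromal, half
    effect) — plus ``n_control`` controls (default: same count), each reading
    ``n_sentences`` sentences. ``effect_map`` shifts the generating signal
    parameters of the clinical group in between-subject SD units (see
    :data:`COHORT_BASELINES`); all-zero means a null cohort.

    Returns ``(recordings, truth)`` where ``truth`` maps participant_id to
    its drawn signal parameters.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 participants per group")
    effect_map = DEFAULT_EFFECT_MAP if effect_map is None else effect_map
    n_control = n_per_group if n_control is None else n_control
    rng = np.random.default_rng(seed)
    recs, truth = [], {}

    def draw_params(shift_scale: float):
        out = {}
        for name, (mu, sd) in COHORT_BASELINES.items():
            shift = effect_map.get(name, 0.0) * sd * shift_scale
            out[name] = float(rng.normal(mu + shift, sd))
        out["pause_dur"] = max(0.05, out["pause_dur"])
        out["f0_var"] = max(0.1, out["f0_var"])
        return out

    roster = [("C%02d" % i, "control", 0.0) for i in range(n_control)]
    for i in range(n_per_group):
        sub = "ALS+B" if i % 2 == 0 else "ALS-B"
        roster.append(("A%02d" % i, sub, 1.0 if sub == "ALS+B" else 0.5))

    for pid, group, scale in roster:
        sex = "M" if rng.random() < 0.5 else "F"
        wpm = float(rng.normal(180.0 if group == "control" else 140.0, 15.0))
        wpm = max(60.0, wpm)
        params = draw_params(scale)
        truth[pid] = {"group": group, **params}
        for s in range(1, n_sentences + 1):
            dur = float(rng.uniform(*duration_range_s))
            recs.append(
                make_recording(pid, group, sex, params, s, dur, rng, wpm)
            )
    return recs, truth


# ---------------------------------------------------------------------------
# Latent-factor feature tables
# ---------------------------------------------------------------------------

def make_factor_table(
    n_samples: int,
    loadings: np.ndarray,
    uniqueness: np.ndarray,
    seed: int = 0,
    feature_names=None,
    factor_names=None,
):
    """Simulate a feature table with a known latent-factor structure.

    ``rows = factors @ loadings.T + noise`` with iid standard-normal factors
    and noise SD ``sqrt(uniqueness)`` per feature. Returns
    ``(table, factors)`` as pandas DataFrames so the generating factor scores
    are available for recovery tests.
    """
    import pandas as pd

    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    uniqueness = np.asarray(uniqueness, dtype=float)
    p, k = loadings.shape
    if uniqueness.shape != (p,) or np.any(uniqueness <= 0):
        raise ValueError("uniqueness must be positive, one value per feature")
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal((n_samples, k))
    eps = rng.standard_normal((n_samples, p)) * np.sqrt(uniqueness)
    data = eta @ loadings.T + eps
    feature_names = feature_names or [f"x{i+1}" for i in range(p)]
    factor_names = factor_names or [f"F{j+1}" for j in range(k)]
    return (
        pd.DataFrame(data, columns=feature_names),
        pd.DataFrame(eta, columns=factor_names),
    )


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------

def write_recording(rec: MultimodalRecording, outdir, stem: str | None = None):
    """Write one recording as WAV + TSV + JSON metadata sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{rec.participant_id}_s{rec.sentence_id:02d}"
    write_wav(outdir / f"{stem}.wav", rec.audio)
    write_semg(outdir / f"{stem}.semg.tsv", rec.semg)
    meta = {
        "participant_id": rec.participant_id,
        "group": rec.group,
        "sex": rec.sex,
        "speaking_rate_wpm": rec.speaking_rate_wpm,
        "sentence_id": rec.sentence_id,
    }
    (outdir / f"{stem}.json").write_text(json.dumps(meta, indent=1))
    return stem
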