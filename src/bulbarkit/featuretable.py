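"""Per-sample feature assembly and cohort runs.

``extract_all_features`` orchestrates the full chain for one synchronized
recording — sEMG conditioning, pause/speech segmentation, then the seven
construct blocks (prosody, pause, functional connectivity, amplitude,
rhythm, complexity, regularity) — and returns the 60 named features. A
stage failure marks its features missing (NaN) with a reason code; the
sample only fails hard when more than 20% of features are missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ampgraph, imc, rhythm, rqa, speechseg, wpdent
from .sigio import (
    SEMG_CHANNELS,
    MultimodalRecording,
    PreprocessConfig,
    burst_epoch_concat,
    preprocess_semg,
    rectify,
)

logger = logging.getLogger("bulbarkit")

#: The frozen 60-feature inventory, grouped by construct.
FEATURE_GROUPS = {
    "prosody": ("sdevF0.st", "iqrF0.st", "meanF0.st"),
    "pause": ("MeanDur_intrapause", "SdevDur_intrapause", "pct_intrapause"),
    "connectivity": tuple(
        f"IMC_{a}_{b}_{band}"
        for a, b in imc.MUSCLE_PAIRS
        for band in ("theta_alpha", "beta", "gamma")
    ),
    "amplitude": ("density_RTEMP", "density_RMAS", "density_RABD", "density_audio"),
    "rhythm": tuple(
        f"{metric}_{ch}"
        for ch in SEMG_CHANNELS
        for metric in ("mod_depth_theta", "PSI_delta_theta", "PSI_theta_beta.gamma")
    ) + tuple(
        f"hbenvlp_{metric}_{band}"
        for band, _, _ in rhythm.CRITICAL_BANDS
        for metric in ("mod_depth_theta", "PSI_delta_theta", "PSI_theta_beta.gamma")
    ),
    "complexity": ("DET_RTEMP", "DET_RMAS", "DET_RABD")
    + tuple(f"DET_mfcc{i}" for i in range(1, 14)),
    "regularity": ("ShanEn_RTEMP", "ShanEn_RMAS", "ShanEn_RABD", "ShanEn_audio"),
}

FEATURE_NAMES = tuple(n for names in FEATURE_GROUPS.values() for n in names)
assert len(FEATURE_NAMES) == 60

METADATA_COLUMNS = ("participant_id", "sentence_id", "group", "sex",
                    "speaking_rate_wpm")


@dataclass
class PipelineConfig:
    """Every numeric constant of the extraction chain in one place."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: speechseg.SegmentationParams = field(
        default_factory=speechseg.SegmentationParams)
    f0: speechseg.F0Params = field(default_factory=speechseg.F0Params)
    coherence: imc.CoherenceParams = field(default_factory=imc.CoherenceParams)
    bands: imc.BandDefinition = field(default_factory=imc.BandDefinition)
    rhythm: rhythm.RhythmParams = field(default_factory=rhythm.RhythmParams)
    rqa_semg: rqa.RQAParams = field(
        default_factory=lambda: rqa.RQAParams(**rqa.SEMG_RQA))
    rqa_mfcc: rqa.RQAParams = field(
        default_factory=lambda: rqa.RQAParams(**rqa.MFCC_RQA))
    wpd: wpdent.WPDConfig = field(default_factory=wpdent.WPDConfig)
    #: cap on RQA 1-s segments per sEMG channel (None = analyze all)
    rqa_max_segments: int | None = 2
    max_missing_fraction: float = 0.20


@dataclass
class FeatureVector:
    """The 60 named features for one sample, with missing-reason codes."""

    values: dict
    missing: dict  # name -> reason

    def __post_init__(self):
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError("feature vector must carry the frozen 60-name inventory")

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


def extract_all_features(
    rec: MultimodalRecording, config: PipelineConfig | None = None
) -> FeatureVector:
    """Run the full extraction chain on one recording."""
    config = config or PipelineConfig()
    values = {name: np.nan for name in FEATURE_NAMES}
    missing: dict[str, str] = {}

    def run(stage_name, names, fn):
        try:
            result = fn()
        except Exception as exc:  # stage failure -> missing features
            logger.warning("stage %s failed: %s", stage_name, exc)
            for n in names:
                missing[n] = f"{stage_name}: {exc}"
            return None
        if isinstance(result, dict):
            for n in names:
                values[n] = result[n]
        return result

    # -- conditioning ------------------------------------------------------
    semg = {ch: preprocess_semg(rec.semg[ch], config.preprocess)
            for ch in SEMG_CHANNELS}
    rectified = {ch: rectify(ts) for ch, ts in semg.items()}
    seg = speechseg.segment_speech_pauses(
        rec.audio, config.segmentation, rec.speaking_rate_wpm)

    # -- prosody -----------------------------------------------------------
    def prosody():
        trace = speechseg.extract_f0(rec.audio, rec.sex, config.f0)
        return speechseg.prosody_features(trace)

    run("prosody", FEATURE_GROUPS["prosody"], prosody)

    # -- pause -------------------------------------------------------------
    run("pause", FEATURE_GROUPS["pause"], lambda: speechseg.pause_features(seg))

    # -- functional connectivity ------------------------------------------
    def connectivity():
        epoched = {}
        for ch in SEMG_CHANNELS:
            epoched[ch], _ = burst_epoch_concat(rectified[ch], config.preprocess)
        specs = {}
        for a, b in imc.MUSCLE_PAIRS:
            n = min(epoched[a].n, epoched[b].n)
            xa = epoched[a].with_samples(epoched[a].samples[:n])
            xb = epoched[b].with_samples(epoched[b].samples[:n])
            specs[(a, b)] = imc.coherence_spectrum(xa, xb, config.coherence)
        return imc.band_coherence_features(specs, config.bands)

    run("connectivity", FEATURE_GROUPS["connectivity"], connectivity)

    # -- amplitude ---------------------------------------------------------
    run("amplitude", FEATURE_GROUPS["amplitude"],
        lambda: ampgraph.amplitude_features(semg, rec.audio))

    # -- rhythm ------------------------------------------------------------
    def rhythm_block():
        semg_envs = {
            ch: rhythm.envelope_100hz(rectified[ch], seg, config.rhythm)
            for ch in SEMG_CHANNELS
        }
        cb_envs = rhythm.cochlear_critical_envelopes(rec.audio, seg, config.rhythm)
        return rhythm.rhythm_feature_block(semg_envs, cb_envs, config.rhythm)

    run("rhythm", FEATURE_GROUPS["rhythm"], rhythm_block)

    # -- complexity --------------------------------------------------------
    run("complexity_semg", FEATURE_GROUPS["complexity"][:3],
        lambda: rqa.semg_determinism_features(
            semg, config.rqa_semg, max_segments=config.rqa_max_segments))
    run("complexity_mfcc", FEATURE_GROUPS["complexity"][3:],
        lambda: rqa.mfcc_determinism_features(rec.audio, config.rqa_mfcc))

    # -- regularity --------------------------------------------------------
    run("regularity", FEATURE_GROUPS["regularity"],
        lambda: wpdent.regularity_features(semg, rec.audio, config.wpd))

    if len(missing) > config.max_missing_fraction * len(FEATURE_NAMES):
        raise RuntimeError(
            f"{len(missing)}/{len(FEATURE_NAMES)} features missing: {missing}")
    return FeatureVector(values=values, missing=missing)


def run_cohort(
    recordings, config: PipelineConfig | None = None, progress: bool = False
) -> pd.DataFrame:
    """Extract features for every recording; one row per (participant, sentence)."""
    recordings = list(recordings)
    if not recordings:
        raise ValueError("empty cohort")
    keys = [(r.participant_id, r.sentence_id) for r in recordings]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (participant, sentence) keys in cohort")
    rows, report = [], []
    for i, rec in enumerate(recordings):
        fv = extract_all_features(rec, config)
        row = {
            "participant_id": rec.participant_id,
            "sentence_id": rec.sentence_id,
            "group": rec.group,
            "sex": rec.sex,
            "speaking_rate_wpm": rec.speaking_rate_wpm,
        }
        row.update(fv.values)
        rows.append(row)
        if fv.missing:
            report.append((rec.participant_id, rec.sentence_id, fv.missing))
        if progress and (i + 1) % 20 == 0:
            logger.info("extracted %d/%d samples", i + 1, len(recordings))
    table = pd.DataFrame(rows)
    if report:
        logger.warning("%d sample(s) had missing features", len(report))
    table.attrs["missing_report"] = report
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
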