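# Methods

This note documents what each stage of the pipeline computes, the
assumptions behind it, the tunable constants and their defaults, what the
synthetic-data generator does and does not emulate, and the choices made
where the underlying method left the design open.

## Signals and preprocessing

A sample is one spoken sentence: mono audio at 22,050 Hz synchronized
with three jaw sEMG channels at 2,000 Hz (right anterior temporalis,
masseter, anterior belly of digastric). Every sEMG channel passes through
a 60-Hz IIR notch (Q = 30) and a 4th-order Butterworth 20-Hz high-pass,
both applied forward–backward so the chain is zero-phase, followed by DC
removal. The realized responses are what the tests assert: ≥ 30 dB
attenuation at 60 Hz, ≥ 20 dB at 5 Hz, passband ripple under 1 dB.

**Burst epoching (coherence front end).** Coherence is estimated on a
concatenation of stationary 1-s epochs centered on activity bursts of the
rectified signal. The burst detector operates on a 100-ms moving-RMS
envelope and thresholds it with an Otsu split *of the log-envelope*,
accepted only when the active class's geometric mean exceeds the
quiescent class's by a factor of 3 (`burst_contrast_min`). The log domain
matters: muscle activity sits decades above the instrument floor while
within-burst fluctuation is comparatively small, and an additive
median + k·MAD rule fails at the high duty cycles speech produces (the
median lands inside the bursts). Records with no amplitude contrast
(baseline noise only) therefore yield a "no supra-threshold activity"
error rather than spurious epochs. Bursts shorter than the 1-s epoch get
one centered epoch; longer activity is tiled with non-overlapping epochs.
A cheap stationarity proxy discards epochs whose first/second-half RMS
ratio exceeds 3.

## Pause and prosody

Speech-pause segmentation thresholds a 10-ms RMS envelope at 0.04 × the
waveform's peak absolute amplitude. The 0.04 constant is interpreted as
*relative* to peak so the segmentation is recording-gain invariant.
Sub-threshold runs ≥ 150 ms become pauses; supra-threshold runs < 35 ms
are absorbed into the adjacent pause. Both duration minima scale by
(160 / actual WPM): slower speakers are held to proportionally longer
minima (`scale_direction` flips this if needed). Pause statistics use the
sample SD; a single pause has SD 0; a pauseless sample reports (0, 0, 0).

f0 is tracked by frame-wise normalized cross-correlation (window 20 ms
for male, 10 ms for female voices; 10-ms hop; search range 60–300 Hz male
/ 100–500 Hz female; voicing threshold 0.5 on the normalized peak).
Because a periodic frame correlates equally at every integer multiple of
its period, the tracker picks the shortest-lag local maximum within 95%
of the global peak — the standard guard against octave errors — and
refines it by parabolic interpolation. Prosody features are the mean,
population SD, and IQR of voiced f0 on the semitone scale; the reference
is 1 Hz, which only translates the mean.

## Intermuscular coherence

Magnitude-squared coherence per muscle pair from Welch estimates with a
1,024-point Hamming window, 75% overlap, 4,096-point FFT (bin width
≈ 0.49 Hz). Band features are means over half-open bands [lo, hi):
theta/alpha 4–12, beta 12–30, low gamma 30–60 Hz. The independence
significance level is S = 1 − 0.05^(1/(L̂−1)). For L̂ we use a
variance-equivalent independent-segment count, K × 0.52 for a Hamming
window at 75% overlap, with the factor exposed in `CoherenceParams`
(`l_hat_factor`) because the literature's exact overlap adjustment is not
fully specified. Gating is applied to band *means*: a gated feature is
either 0 or ≥ S, never in between. On single sentences (few Welch
segments) S is high and most band means gate to zero — a property of the
method at short record lengths, not a defect; the Monte-Carlo tests use
60–120-s records where the estimator has power. When the per-channel
epoch concatenations differ in length, the pair is trimmed to the shorter
one before the spectra are taken.

## Visibility-graph amplitude features

The signal is reduced to the SD of non-overlapping 50-ms blocks
(1,103 samples for audio — the convention fixed upstream despite
22,050 × 0.05 = 1,102.5 — and 100 for sEMG; denominator L−1; partial tail
block dropped). The natural visibility criterion is strict, so collinear
runs contribute only adjacent edges; density = 2m/(M(M−1)) is invariant
to amplitude scaling by construction. The O(M²) sweep implementation is
checked against an O(M³) brute-force oracle in the tests.

## Rhythm

Envelopes are Hilbert magnitudes resampled to 100 Hz (polyphase
anti-aliasing), computed after pause excision. Theta modulation depth is
the theta-band (2.5–12 Hz) share of the demeaned envelope's power
spectrum (Hamming-windowed FFT, ≥ 2,048 points). The DC bin is excluded
from the normalization — with the raw envelope's mean included, the
metric saturates near 0 for every signal and loses all contrast.

PSI band-passes the envelope with 4th-order zero-lag Butterworth filters
at delta 0.9–2.5, theta 2.5–12, beta/gamma 12–40 Hz, takes instantaneous
phases from the analytic signal, and reports the modulus of the
time-averaged phasor of nφ_slow − mφ_fast (2:1 for delta–theta, 3:1 for
theta–beta/gamma). The averaging operator is required — without it the
modulus of a unit phasor is identically 1. The record must cover at least
3 cycles of the slower band's center frequency. The null PSI decays as
roughly N^(−1/2) with record length, which the tests check at two
lengths.

Acoustic envelopes come from a 28-band filterbank spanning 100–10,000 Hz
with edges equally spaced on the ERB-rate scale (E = 21.4·log10(1 +
0.00437 f)) as a cochlear-map approximation, each band a 4th-order
zero-lag Butterworth slice. Narrowband envelopes whose geometric-mean
center falls in 100–300, 300–800, 1,000–3,000, or 3,000–8,000 Hz are
averaged into that critical band (`combine="sum"` selectable); centers in
the 800–1,000 and 8,000–10,000 Hz gaps belong to no band. Averaging
commutes with the zero-phase band-pass, so filtering the combined
envelope equals combining filtered members.

## Complexity (RQA)

Series are z-scored, delay-embedded, and thresholded at ε × the maximal
pairwise embedded distance (scale-free; a fraction-of-SD mode is
selectable). Recurrence uses the Euclidean norm; the line of identity is
excluded (Theiler window 1); diagonal lines count from l_min = 2. DET is
the fraction of recurrence points on qualifying diagonals. sEMG channels
are analyzed in non-overlapping 1-s segments with (m=30, τ=5, ε=0.1) and
averaged; `rqa_max_segments` (default 2 in `PipelineConfig`) caps the
segments per channel, evenly spread over the record, to bound cohort
runtime — the per-segment DETs of stationary speech sEMG are close, so
the cap mainly trades variance.

MFCCs are computed in-house: 25-ms Hamming frames at a 10-ms hop, power
spectrum, 26 triangular mel filters to fs/2, log, orthonormal DCT-II,
keeping c1–c13 ("first 13", excluding the energy coefficient c0). Each
coefficient series gets its own DET with (m=3, τ=15, ε=0.2).

## Regularity (wavelet-packet entropy)

A 3-level wavelet packet decomposition (Daubechies-4) yields 8 terminal
nodes in natural frequency order. The default boundary mode is
periodization, which makes the tree exactly orthogonal so node energies
sum to the input energy to float precision (symmetric padding is
selectable but leaks edge energy). Per node, Shannon entropy
−Σ s²·ln s² is computed over squared coefficients normalized by the
**total** signal energy, and the 8 node entropies are averaged. The
global normalization is deliberate: it makes the index sensitive to how
energy distributes *across* nodes, so a narrowband (regular) signal
scores low and broadband noise scores high. Normalizing each node to unit
energy independently inverts that ordering — a pure sine spreads
uniformly over time within its node (per-node entropy ln N − 0.31 versus
ln N − 0.42 for Gaussian coefficients) — and would contradict the
metric's meaning; it remains available as `normalization="node"` for
comparison. Natural log throughout. Zero-energy nodes contribute 0 with a
warning.

## Feature assembly

`extract_all_features` runs conditioning, segmentation, then the seven
construct blocks, producing exactly the frozen 60-name inventory (tested
against a checked-in manifest). A stage failure records its features as
NaN with a reason code; the sample fails hard only if > 20% of features
are missing. Cohort runs key rows by (participant, sentence) and reject
duplicates. CSV round-trips preserve 12 significant digits.

## Validation layer

* **Screening:** Cohen's d with pooled SD; |d| > 0.5 retained; groups
  ordered lexicographically so the sign is label-deterministic; missing
  values dropped per feature; zero-pooled-SD features flagged out.
* **CFA:** simple-structure model (each feature on one factor, factors
  freely correlated, diagonal uniqueness) estimated by minimizing the ML
  discrepancy log|Σ| + tr(SΣ⁻¹) − log|S| − p with L-BFGS-B; factor
  correlations parameterized through tanh with a positive-definiteness
  guard; uniquenesses log-parameterized (bounded above 10⁻⁶; values at
  the bound are flagged as Heywood cases). CFI and RMSEA come from the
  model and independence-baseline chi-squares; features with |loading| <
  0.5 are pruned in a single pass and the model refit once. Factors
  reduced to a single indicator are identified by fixing the loading at 1
  with near-zero uniqueness, so their Bartlett score reproduces the
  z-scored feature. Bartlett scores are (ΛᵀΨ⁻¹Λ)⁻¹ΛᵀΨ⁻¹z per row —
  unbiased for the generating factors, which the tests verify by
  regression slope. The default 10-factor assignment maps the inventory
  onto Pros_a, Pause_a, IMC_e, Amp_e, Amp_a, Rhy_e, Rhy_a, Comp_e,
  Comp_a, Reg_e; acoustic regularity (ShanEn_audio) has no factor.
* **Reliability:** Cronbach's alpha, k/(k−1)·(1 − Σvarᵢ/var(sum));
  undefined for single-item factors.
* **Group tests from summaries:** pooled-variance one-way ANOVA from
  (M, SD, n) — equal to a full ANOVA on any raw data with those
  summaries, which a test verifies — and Yates-corrected chi-square for
  2×2 counts (the continuity correction is required to reproduce the
  published sex comparison). BH-FDR adjustment via statsmodels.
* **ML harness:** repeated stratified k-fold (5 × 10 default);
  out-of-fold predictions pooled per repeat, metrics averaged over
  repeats; learners are scikit-learn's LinearRegression/
  LogisticRegression, RandomForest (500 trees, impurity-decrease
  importances), and RBF-SVM (γ = 1/(p·var), C = 1, inputs standardized
  inside the fold pipeline). Binary metrics: accuracy, sensitivity,
  specificity, ROC AUC (positive class = lexicographically last label).
  Multiclass: per-pair accuracy/sensitivity/specificity on pooled
  predictions plus an overall AUC averaged over one-vs-one pairs.
  Everything is seeded and bit-reproducible.

## Synthetic data: what it emulates, and what it does not

Voiced audio is a band-limited sawtooth source (harmonics to 5 kHz, 1/k
roll-off) following a scheduled f0 contour, amplitude-modulated at a
syllable rate (default 5 Hz), silenced over scheduled pauses with 10-ms
raised-cosine edges. sEMG channels are burst-gated (50-ms raised-cosine
ramps) mixtures c·shared + (1−c)·private of band-limited Gaussian drives
(default 15–30 Hz) plus a small baseline noise floor, so the drive-band
coherence is controlled by the single coupling c. Cohorts draw
per-participant parameters (coupling 0.60 ± 0.10, AM depth 0.60 ± 0.10,
pause length 0.30 ± 0.05 s, f0 excursion 2.0 ± 0.5 st) from the baseline
distributions; the clinical group's means are shifted by `effect_map`
in between-subject SD units, with the symptomatic subgroup (ALS+B)
receiving the full shift and the prodromal subgroup (ALS−B) half — the
graded severity the battery is meant to resolve. Effects are injected at
the *signal* level, never at the feature level, so a group difference
must survive the entire extraction chain to appear in the table.
Sentences default to 3.0–3.8 s with two scheduled pauses, 19 per
participant.

Not emulated: motor-unit physiology (recruitment, firing statistics,
conduction velocity), articulated phonemes/formant dynamics,
co-articulation, microphone/room acoustics, electrode artifacts, or any
cross-modal phase relationship beyond shared burst timing. Passing tests
therefore demonstrate that the pipeline measures what it claims on
signals with known structure — not that the features separate real
clinical populations.

## Problem sizes and numerical choices

The cohort integration test runs the full 23 × 19 = 437-sample synthetic
cohort with `rqa_max_segments = 1`; recovery tests use n = 2,000 rows for
the factor model and 48–120-sample cohorts for the ML checks — sizes at
which every estimator involved is stable. Monte-Carlo properties
(coherence nulls, PSI nulls) average 5–20 seeded runs of 60–120-s
records. Degenerate inputs fail loudly: constant series (RQA z-score),
zero-energy signals (entropy), unvoiced samples (prosody), sub-epoch
records (coherence), all-silent audio (single pause with a warning).

## Known limitations

* The CFA is a bespoke ML optimizer, adequate for simple-structure
  models of this size but without the robust standard errors, missing-
  data handling, or fit-index zoo of dedicated SEM software.
* L̂'s overlap correction (0.52 factor) is a documented stand-in; the
  significance gate shifts accordingly if it is changed.
* Burst detection assumes the record contains *some* amplitude contrast;
  fully tonic records with no quiet margin are indistinguishable from
  scaled noise without an absolute calibration and are rejected.
* The f0 tracker has no pitch-halving correction beyond the range limits
  and the 95%-peak rule; extreme creak or diplophonia would need a
  dedicated tracker.
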