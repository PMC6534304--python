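# Methods

## Problem and pipeline

`vocemark` implements a purely acoustic analysis of memory-clinic
conversations that separates patients with neurodegenerative disorders (ND)
from patients with functional memory disorder (FMD). The input is a mono
conversation recording plus a speaker-turn annotation; only the patient's
own turns are analysed. The pipeline is

1. **canonicalization** — WAV decode, mono mixdown, polyphase resampling to
   16 kHz, amplitude in [-1, 1]; optional spectral noise gating;
2. **feature extraction** — 51 features per analysis unit (a whole
   recording, or a one-minute window of patient talk), in three blocks:
   15 speech/silence statistics, 21 phonation statistics, 15
   duration-weighted spectral statistics;
3. **feature selection** — SVM-wrapped recursive feature elimination (RFE),
   random-forest impurity importances, or per-feature Mann-Whitney U
   ranking;
4. **evaluation** — five classifier families (linear SVM, random forest,
   AdaBoost, MLP, linear SGD) under leakage-controlled cross-validation:
   nested stratified 5-fold for per-recording tables, leave-one-group-out
   (LOGO, all segments of one patient held out together) for per-segment
   tables. Z-scoring and feature ranking are always fitted inside training
   folds.

Because clinical recordings of this kind cannot be shared, the package
ships a synthetic conversation generator with ground-truth logs; every
stage is validated against that ground truth.

## Feature definitions

**Speech/silence block (15).** An energy voice-activity detector computes
RMS intensity in non-overlapping 10 ms frames per patient turn; frames more
than 25 dB below the track's 95th-percentile intensity are silent. Silent
runs ≥ 0.25 s are pauses, voiced runs ≥ 0.5 s are speech segments; shorter
runs merge into the surrounding state (short silences are resolved first).
The 10 ms non-overlapping window was chosen so that a segment boundary is
localized within one hop by construction; a longer overlapping window
(e.g. 25 ms) triggers on any partial overlap with speech and biases
boundaries outward by more than a hop. Features: mean response latency
(gap from the preceding non-patient turn), max/mean/SD of pause and speech
durations, ratios of max pause, total pause, total speech and pause count
to the total patient turn time, the max-speech/max-pause ratio, and
mean/SD/variance of "long" speech segments ≥ 0.8 s (a duration proxy that
excludes filler-like bursts). Sixteen candidate names exist; the default
schema drops `ratio_max_speech_total` to give the canonical 15, and a
config switch can restore it. Degenerate denominators (e.g. no pauses)
yield 0 with a warning rather than NaN so feature matrices stay complete.

**Phonation block (21).** Autocorrelation pitch tracking (40 ms Hann
frames, 10 ms hop, window-autocorrelation bias correction, parabolic peak
interpolation, voicing threshold r ≥ 0.45, candidate range 75–500 Hz, with
subharmonic suppression preferring a half-lag whose correlation is ≥ 95%
of the best peak). Glottal pulses are marked once per period by a
sequential peak walker: anchor on the strongest peak of the first period
of each voiced run, then step one local period at a time, snapping to the
nearest waveform maximum with parabolic sub-sample refinement. Stepping
relative to the last *found* pulse prevents frame-level F0 bias from
accumulating into drift — the property that makes sub-percent jitter
measurable. Base measures per utterance: mean F0; HNR/NHR from the voicing
strength r via `hnr = 10·log10(r/(1−r))` and `nhr = (1−r)/r` (so
`nhr = 10^(−hnr/10)` exactly per frame); jitter(local) and shimmer(local)
as mean absolute consecutive-cycle period/amplitude difference over the
mean, in percent, with population denominators; number and degree of voice
breaks (inter-pulse gaps > 16 ms that also exceed 1.25× the local median
period — the bare 16 ms rule would flag normal cycles below 62.5 Hz).
Long silent stretches inside a turn leave long inter-pulse gaps and count
as voicing interruptions, as in standard voice-report practice. Each
measure is summarized by mean, SD and variance across the patient's
utterances (population statistics; a single utterance gives SD = 0).
Utterances shorter than three periods are skipped.

**Spectral block (15).** Per 25 ms frame (10 ms hop): pre-emphasis 0.97,
Hamming window, power spectrum (FFT 512 at 16 kHz), 26 triangular mel
filters over 0–8 kHz. `fbank` = 26 log filter energies (floor 1e-10);
`mfcc` = first 13 DCT-II coefficients of the fbank vector, excluding the
pure-gain c0; `ssc` = each filter's share of total filter energy (the
normalized-subband-energy variant — per frame the 26 shares sum to exactly
1 — not the classical frequency-centroid), first 13 retained. Per
utterance the frame-mean coefficient vectors are divided by the utterance
duration, giving averaged weighted spectral coefficients (AWSC, units
1/s): the same spectral content spread over a longer utterance yields
proportionally smaller AWSC, deliberately folding response timing into the
spectral block. Each utterance's AWSC subgroup is scalarized (mean over
coefficients) and mean/SD/min/max/variance are taken across utterances,
giving 5 features per subgroup. Scalarizing before the statistics is the
default; statistics over the pooled utterance × coefficient matrix are the
config alternative.

## Feature selection

* `rfe_rank` — repeatedly fit a linear SVM (C = 1) on standardized
  training rows and drop the feature with the smallest |coefficient|
  (ties drop the later column, for determinism); ranking is reverse
  elimination order.
* `embedded_rank` — mean impurity-decrease importance of a random forest,
  seeded (default 13) for reproducible rankings.
* `mannwhitney_rank` — per-feature two-sided Mann-Whitney U; the reported
  statistic is min(U₁, U₂) (the convention of common statistics packages),
  features with p < 0.05 are selected, ranked by ascending U.

The three routes are exposed both as functions returning a full
`SelectionResult` and as a scikit-learn transformer (`RouteSelector`) so
they compose with Pipelines and cross-validation.

## Validation design

Scenario 1 (one row per patient, 15 + 15): stratified 5-fold outer loop;
on each outer-training set the features are ranked once by the chosen
route (training rows only), and an inner stratified 5-fold loop picks the
feature count (from {10, 22, 51}) and classifier hyper-parameters that
maximize inner validation accuracy; the winning configuration is refit on
the outer-training rows and scored on the held-out fold. Reported accuracy
is mean ± SD over outer folds (the SD is across folds, and is labelled as
such). Sensitivity is ND recall and specificity FMD recall, pooled over
outer test folds.

Scenario 2 (one row per one-minute window of patient talk, with the
patient id as group): leave-one-group-out outer loop (30 splits for 30
patients), grouped 3-fold inner loop. By default the inner loop tunes the
feature count only, with hyper-parameters fixed at mid-grid values — at
~230 segments × 30 outer splits × 5 classifiers a full grid search costs
far more than it changes the outcome on these cohorts. Both segment-pooled
and per-group accuracies are reported, since they differ whenever
per-group accuracies vary.

Hyper-parameter grids: SVM C ∈ {0.01, 0.1, 1, 10}; random forest 60 trees,
depth ∈ {None, 5}; AdaBoost ∈ {40, 80} estimators; MLP one hidden layer
∈ {16, 64}; SGD (hinge) α ∈ {1e-4, 1e-3}. The grids are deliberately
small: at 30 training rows larger grids only add inner-loop variance.

A deliberately leaky mode (ranking features on the full table before
splitting) exists only for tests; on pure-noise features it inflates
apparent accuracy from ~0.5 to ~0.85, which is exactly the bias the
default path is built to exclude.

## Synthetic cohort generator

`synthgen` emulates the structure the analysis relies on, not natural
speech. A conversation alternates synthesized doctor turns (F0 110 Hz —
disjoint from the patient range purely as a debugging aid) with patient
turns; patient turns contain utterances and within-turn pauses; latencies,
utterance lengths and pause durations are drawn per the class's
`DialogueSpec`. Voices are source-filter synthesized: band-limited pulse
kernels placed at instants with per-cycle period jitter `N(0, σ_j·T0)` and
amplitude shimmer `N(0, σ_s)`, shaped by three /a/-like formant resonators
(700/1220/2600 Hz), plus white noise at the power ratio implied by the
target HNR; voice breaks are 30–80 ms silent gaps at a Poisson rate. Every
pulse instant, pause, latency and break is logged as ground truth.

Class-conditional defaults (full scale): patient talk time lognormal with
mean 11.5 min (SD 6.3) for FMD vs 6.2 min (SD 4.5) for ND — the
moment-matched lognormal avoids the upward bias a truncated normal adds to
the class means; utterance length mean 3.5 s vs 2.2 s; response latency
0.8 s vs 1.6 s; within-turn pause rate 0.15/s vs 0.30/s; pause duration
0.45 s vs 0.75 s; voice-break rate 0.05/s vs 0.20/s. The two classes share
identical F0, jitter, shimmer and HNR distributions: in clinical FMD/ND
data the discriminative features are pause/utterance timing, voice breaks
and (weakly, via duration weighting) the spectral statistics — baseline
phonation quality does not separate the groups, and the generator mirrors
that structure so that a large minority of the 51 features is genuinely
uninformative. Between-patient heterogeneity (`PATIENT_SD`) draws each
patient's parameters around the class means; without it the classes would
be deterministically separable and selection/validation would be trivial.

`effect_scale` interpolates each class's parameters between the pooled
midpoint (0 = exchangeable null cohort) and the full contrast (1).
`time_scale` multiplies per-patient talk time only, leaving all per-second
statistics untouched; the scenario-2 window scales with it (60 s ×
`time_scale`), so the per-segment sample structure (~230–300 segments,
~60–68% FMD) is preserved at any scale. Seed-averaged studies in the test
suite and the acceptance script run at `time_scale = 0.15` (window 9 s),
the problem size at which a five-seed, two-scenario study completes in
minutes on one CPU; results at that scale reproduce the qualitative
pattern (selection helps; per-segment evaluation scores lower than
per-recording) rather than any specific clinical accuracy.

What the generator does **not** model: lexical content or intelligible
speech, accompanying persons, channel/room acoustics, dependence between
pause behaviour and voice quality within a patient (parameters are drawn
independently), or spectral-timbre differences between classes. Passing
tests therefore demonstrate that the measurement and validation machinery
is correct and leakage-free — not that real FMD/ND cohorts separate at any
particular accuracy.

## Numerical choices and edge cases

* Resampling: `scipy.signal.resample_poly` (anti-aliased polyphase).
* Noise gate: 2048-point STFT at 50% overlap, per-bin threshold = noise
  mean + 1.5 SD, attenuation smoothed over 3 frames in the log domain (so
  boundary frames stay attenuated).
* 16-bit WAV I/O uses the symmetric 1/32767 scale so integer samples
  round-trip bit-exactly.
* Pitch strength is clipped to [1e-6, 1 − 1e-6] before the HNR logit.
* Pulse walker amplitude gate: predictions whose local peak falls below
  0.25× the run's 98th-percentile amplitude emit no pulse (silent gaps).
* Empty/degenerate inputs (no pauses, no voiced frames, a single
  utterance) produce 0-valued features with warnings, never NaN.
* All randomness flows through `numpy.random.Generator` seeded from
  explicit SeedSequences; per-recording substreams derive from
  (cohort seed, recording index).

## Known limitations

* Jitter above ~2% is overestimated (the peak walker starts period-hopping
  when perturbations approach the search window); rank order is preserved,
  which is what the recovery checks assert.
* The energy VAD has no spectral model; broadband noise at speech-like
  levels would be labelled speech. Real recordings should be noise-gated
  first.
* The LOGO inner loop's grouped 3-fold split does not stratify by class;
  with very few groups per class an inner fold can be single-class, in
  which case accuracy-based tuning degenerates to the first grid point.
* TextGrid parsing covers ordinary interval tiers (long/short text form),
  not every dialect of the format.
* At 15 + 15 patients the benefit of feature selection over using all 51
  features is real but small (1–2 accuracy points seed-averaged) and noisy:
  individual five-seed batches can show a tie. The SVM ≥ 0.9 bar and the
  scenario-2 < scenario-1 ordering are robust across seed batches.
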