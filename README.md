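# vocemark

Acoustic voice-biomarker analysis of memory-clinic conversations:
distinguishing neurodegenerative disorders (ND — Alzheimer's disease,
amnestic MCI, frontotemporal or vascular dementia) from functional memory
disorder (FMD — subjective memory concern without objective deficit) using
nothing but the sound of the patient's answers to a neurologist's
questions.

Specialist memory clinics face long waits, and most referred patients turn
out to have functional rather than degenerative memory problems. Speech
timing and voice quality change early in neurodegeneration — more and
longer pauses, shorter utterances, slower responses, more voicing
interruptions — so a purely acoustic screen, which needs no speech
recognition or transcription, is an attractive triage signal. `vocemark`
is a tested, reusable implementation of that analysis for researchers in
computational paralinguistics and clinical speech science.

## What it computes

From a conversation WAV plus a speaker-turn annotation (TSV or Praat
TextGrid), the pipeline isolates the patient's turns and extracts **51
acoustic features** per sample:

| block | n | content |
|---|---|---|
| speech/silence | 15 | pause/speech-segment duration statistics (pause = silence ≥ 0.25 s, speech ≥ 0.5 s), ratios to total turn time, mean response latency, statistics of "long" (≥ 0.8 s) segments |
| phonation | 21 | mean/SD/variance across utterances of F0, HNR, NHR, jitter(local), shimmer(local), number and degree of voice breaks (inter-pulse gaps > 16 ms) |
| spectral | 15 | mean/SD/min/max/variance of duration-weighted MFCC, log mel-filterbank and subband-energy-share coefficients (AWSC: per-utterance frame means divided by utterance duration, units 1/s) |

Feature selection offers three routes — linear-SVM recursive feature
elimination (RFE), random-forest embedded importances, and per-feature
Mann-Whitney U ranking (statistic reported as min(U₁, U₂), selection at
p < 0.05) — and evaluation runs five classifiers (linear SVM, random
forest, AdaBoost, MLP, linear SGD) under leakage-controlled validation:
nested stratified 5-fold for per-recording samples, leave-one-group-out
for one-minute segments (all segments of a patient stay on one side of
every split). Standardization `(x − μ)/σ` and feature ranking are fitted
on training folds only.

Clinical recordings of this kind are private, so the package includes a
**synthetic conversation generator** (`vocemark.synthgen`): source-filter
voices (glottal pulse trains with controllable jitter, shimmer, HNR and
voice-break rate, /a/-like formants) arranged into doctor/patient
dialogues with class-contrasted talk time, pause behaviour and utterance
lengths, plus ground-truth logs of every pause, pulse and break. All tests
and the acceptance script run end-to-end on generated cohorts.

## Worked example

```bash
# generate a 15+15 synthetic cohort at 15% talk scale
vocemark synth --n-per-class 15 --time-scale 0.15 --seed 7 --out cohort/

# extract the 51-feature table (one row per recording)
vocemark extract --manifest cohort/manifest.csv --out features.csv

# evaluate with RFE-selected features under nested 5-fold CV
vocemark evaluate --features features.csv --route rfe --seed 7 --out report.json
```

or in Python:

```python
from vocemark.pipeline import RunConfig, run_all

report, provenance = run_all(RunConfig(seed=7, time_scale=0.15, route="rfe"))
for regime in report.reports:
    print(regime, round(report.mean_accuracy(regime), 3))
```

which prints, for this seed:

```
all 0.927
rfe 0.947
```

i.e. the five-classifier mean accuracy over outer folds is 0.927 using all
51 features and 0.947 after per-fold RFE selection — selection helps
because a substantial minority of the features carries no class signal on
these cohorts (by design: baseline phonation quality does not differ
between the classes, only timing and voice-break behaviour do).
`report.json` additionally lists per-classifier accuracy mean ± SD across
folds, the number of selected features, and pooled sensitivity (ND recall)
and specificity (FMD recall).

See `docs/methods.md` for the full description of the feature
definitions, the validation design, what the generator does and does not
emulate, and known limitations.

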