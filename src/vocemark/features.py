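"""The 51-feature acoustic schema and per-track extraction.

The feature vector partitions into three blocks:

* 15 speech/silence statistics (pause and speech-segment durations, ratios
  against total patient turn time, response latency),
* 21 phonation/voice-quality statistics (mean/STD/variance across
  utterances of F0, HNR, NHR, shimmer, jitter, voice-break count/degree),
* 15 duration-weighted spectral statistics (mean/STD/min/max/variance of
  scalarized AWSC per subgroup MFCC/Fbank/SSC).

Column order is frozen so feature CSVs are comparable across runs.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .audio_io import PatientTrack
from .phonation import PHONATION_FEATURES, phonation_features
from .segmental import (SEGMENTAL_FEATURES, detect_segments,
                        segmental_features)
from .spectral import SPECTRAL_FEATURES, spectral_features_for_track

FEATURE_COLUMNS: tuple[str, ...] = (
    SEGMENTAL_FEATURES + PHONATION_FEATURES + SPECTRAL_FEATURES)

N_FEATURES = len(FEATURE_COLUMNS)
assert N_FEATURES == 51

LABELS = ("FMD", "ND")
POSITIVE_LABEL = "ND"


def extract_feature_row(track: PatientTrack,
                        pause_min: float = 0.25, speech_min: float = 0.5,
                        long_min: float = 0.8,
                        intensity_threshold: float = 25.0) -> dict[str, float]:
    """All 51 features for one patient track (a recording or a segment)."""
    seg = detect_segments(track, pause_min=pause_min, speech_min=speech_min,
                          intensity_threshold=intensity_threshold)
    row = segmental_features(seg, track, long_min=long_min)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        row.update(phonation_features(track))
    row.update(spectral_features_for_track(track))
    return {name: row[name] for name in FEATURE_COLUMNS}


def feature_table(rows: list[dict[str, float]], labels: list[str],
                  group_ids: list[str]) -> pd.DataFrame:
    """Assemble a feature table: 51 feature columns + label + group_id."""
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    if df.isna().any().any():
        raise ValueError("feature table contains missing values")
    df["label"] = labels
    df["group_id"] = group_ids
    return df


def validate_feature_table(df: pd.DataFrame) -> None:
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    for col in ("label", "group_id"):
        if col not in df.columns:
            raise ValueError(f"feature table missing {col!r} column")
    if df[list(FEATURE_COLUMNS)].isna().any().any():
        raise ValueError("feature table contains missing values")
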