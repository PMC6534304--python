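"""Shared fixtures: tiny synthetic cohorts and constructed signals."""

from __future__ import annotations

import numpy as np
import pytest

from vocemark.audio_io import PatientTrack, Waveform
from vocemark.synthgen import CohortSpec, generate_cohort

FS = 16_000


def tone(freq: float, duration: float, fs: int = FS, amp: float = 0.5) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def silence(duration: float, fs: int = FS) -> np.ndarray:
    return np.zeros(int(round(duration * fs)))


def track_from_layout(layout: list[tuple[str, float]],
                      freq: float = 200.0) -> tuple[PatientTrack, list, list]:
    """PatientTrack containing one turn built from (kind, duration) pieces.

    Returns (track, true_speech_intervals, true_pause_intervals).
    """
    pieces, speech, pauses = [], [], []
    t = 0.0
    for kind, dur in layout:
        if kind == "speech":
            pieces.append(tone(freq, dur))
            speech.append((t, t + dur))
        else:
            pieces.append(silence(dur))
            pauses.append((t, t + dur))
        t += dur
    w = Waveform(np.concatenate(pieces), FS)
    return PatientTrack([w], [(0.0, t)], []), speech, pauses


@pytest.fixture(scope="session")
def tiny_cohort():
    """4+4 recordings at 5% talk scale — fast enough for unit tests."""
    spec = CohortSpec(n_per_class=4, seed=11, time_scale=0.05)
    recordings, manifest = generate_cohort(spec)
    return recordings, manifest


@pytest.fixture(scope="session")
def tiny_tables(tiny_cohort):
    """Feature tables (per-recording and per-window) for the tiny cohort."""
    from vocemark.pipeline import extract_features, tracks_from_recordings

    recordings, _ = tiny_cohort
    tracks = tracks_from_recordings(recordings)
    df1 = extract_features(tracks, scenario="recordings", window=3.0)
    df2 = extract_features(tracks, scenario="segments", window=3.0)
    return df1, df2


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
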