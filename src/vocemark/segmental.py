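"""Speech/silence segmentation of patient material and the segmental feature block.

An energy-based voice activity detector labels 10 ms frames of each patient
turn as speech or silence relative to the track's peak intensity. Silent
runs of at least ``pause_min`` (0.25 s) become pauses, voiced runs of at
least ``speech_min`` (0.5 s) become speech segments — matching the common
clinical convention for conversational pause analysis. Speech statistics
"excluding filler words" restrict to segments of at least 0.8 s, treating
shorter bursts as likely fillers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .audio_io import PatientTrack, Waveform

log = logging.getLogger(__name__)

# non-overlapping 10 ms intensity frames: a frame triggers only on energy
# inside its own hop, so segment boundaries are localized within one hop
FRAME_S = 0.010
HOP_S = 0.010

#: canonical order of the 16 candidate segmental features
SEGMENTAL_CANDIDATES = (
    "mean_response_time",
    "max_pause", "mean_pause", "std_pause",
    "max_speech", "mean_speech", "std_speech",
    "ratio_max_pause_total",
    "ratio_max_speech_total",
    "ratio_max_speech_max_pause",
    "ratio_total_pause_total",
    "ratio_total_speech_total",
    "ratio_pause_count_total",
    "mean_long_speech", "std_long_speech", "var_long_speech",
)

#: default 15-feature subset (drops ratio_max_speech_total)
SEGMENTAL_FEATURES = tuple(
    n for n in SEGMENTAL_CANDIDATES if n != "ratio_max_speech_total")


@dataclass
class SegmentSet:
    """Pause and speech intervals (seconds, original-recording time)."""

    pauses: list[tuple[float, float]]
    speech_segments: list[tuple[float, float]]
    total_time: float

    @property
    def pause_durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.pauses])

    @property
    def speech_durations(self) -> np.ndarray:
        return np.array([e - s for s, e in self.speech_segments])


def frame_intensity_db(w: Waveform, frame_s: float = FRAME_S,
                       hop_s: float = HOP_S) -> tuple[np.ndarray, np.ndarray]:
    """Frame RMS intensity in dB with frame-centre times."""
    n = len(w.samples)
    flen = max(1, int(round(frame_s * w.rate)))
    hop = max(1, int(round(hop_s * w.rate)))
    if n < flen:
        pad = np.pad(w.samples, (0, flen - n))
        frames = pad[None, :]
    else:
        n_frames = 1 + (n - flen) // hop
        idx = np.arange(flen)[None, :] + hop * np.arange(n_frames)[:, None]
        frames = w.samples[idx]
    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    db = 20.0 * np.log10(np.maximum(rms, 1e-10))
    times = (np.arange(len(db)) * hop + flen / 2) / w.rate
    return db, times


def _merge_runs(labels: np.ndarray, hop_s: float,
                pause_min: float, speech_min: float) -> np.ndarray:
    """Enforce minimum run lengths: short silences first, then short speech."""
    lab = labels.copy()
    for min_s, state in ((pause_min, False), (speech_min, True)):
        min_frames = int(round(min_s / hop_s))
        runs = _runs(lab)
        for start, stop, value in runs:
            if value == state and (stop - start) < min_frames:
                lab[start:stop] = not state
    return lab


def _runs(lab: np.ndarray) -> list[tuple[int, int, bool]]:
    if len(lab) == 0:
        return []
    change = np.flatnonzero(np.diff(lab.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [len(lab)]))
    return [(int(bounds[i]), int(bounds[i + 1]), bool(lab[bounds[i]]))
            for i in range(len(bounds) - 1)]


def detect_segments(track: PatientTrack, pause_min: float = 0.25,
                    speech_min: float = 0.5,
                    intensity_threshold: float = 25.0) -> SegmentSet:
    """Voice activity detection over all patient turns.

    Frames more than ``intensity_threshold`` dB below the track's
    95th-percentile intensity are silent. The threshold is peak-relative, so
    the segmentation is invariant to amplitude scaling of the waveform.
    """
    if not track.utterance_waveforms:
        raise ValueError("empty patient track")
    per_turn = [frame_intensity_db(w) for w in track.utterance_waveforms]
    all_db = np.concatenate([db for db, _ in per_turn])
    ref = np.percentile(all_db[all_db > -199.0], 95) if np.any(all_db > -199.0) else 0.0
    thresh = ref - intensity_threshold

    pauses: list[tuple[float, float]] = []
    speech: list[tuple[float, float]] = []
    for (db, _times), (t0, t1) in zip(per_turn, track.turn_times):
        voiced = db >= thresh
        voiced = _merge_runs(voiced, HOP_S, pause_min, speech_min)
        n_frames = len(voiced)
        for start, stop, value in _runs(voiced):
            # each frame owns one hop of time; last run extends to turn end
            a = t0 + start * HOP_S
            b = t1 if stop == n_frames else t0 + stop * HOP_S
            if value:
                speech.append((a, b))
            else:
                pauses.append((a, b))
    if not speech:
        log.warning("all-silent patient track: no speech segments detected")
    return SegmentSet(pauses, speech, track.total_turn_time)


def _stats(x: np.ndarray) -> tuple[float, float, float]:
    """(max, mean, std) with 0 for empty input; population std."""
    if len(x) == 0:
        return 0.0, 0.0, 0.0
    return float(np.max(x)), float(np.mean(x)), float(np.std(x))


def segmental_features(seg: SegmentSet, track: PatientTrack,
                       long_min: float = 0.8,
                       feature_names: tuple[str, ...] = SEGMENTAL_FEATURES,
                       ) -> dict[str, float]:
    """The speech/silence feature block (15 features by default).

    All "total turn time" denominators use the patient's summed turn time.
    Degenerate denominators (no pauses, zero total time) yield 0 with a
    warning rather than NaN, keeping downstream feature matrices complete.
    """
    total = track.total_turn_time
    p = seg.pause_durations
    s = seg.speech_durations
    long_s = s[s >= long_min] if len(s) else s

    max_p, mean_p, std_p = _stats(p)
    max_s, mean_s, std_s = _stats(s)
    _, mean_l, std_l = _stats(long_s)

    if len(p) == 0 and len(s) > 0:
        warnings.warn("no pauses detected; pause-ratio features set to 0",
                      stacklevel=2)

    def ratio(a: float, b: float) -> float:
        return a / b if b > 0 else 0.0

    values = {
        "mean_response_time": float(np.mean(track.response_latencies))
        if track.response_latencies else 0.0,
        "max_pause": max_p, "mean_pause": mean_p, "std_pause": std_p,
        "max_speech": max_s, "mean_speech": mean_s, "std_speech": std_s,
        "ratio_max_pause_total": ratio(max_p, total),
        "ratio_max_speech_total": ratio(max_s, total),
        "ratio_max_speech_max_pause": ratio(max_s, max_p),
        "ratio_total_pause_total": ratio(float(p.sum()) if len(p) else 0.0, total),
        "ratio_total_speech_total": ratio(float(s.sum()) if len(s) else 0.0, total),
        "ratio_pause_count_total": ratio(float(len(p)), total),
        "mean_long_speech": mean_l,
        "std_long_speech": std_l,
        "var_long_speech": std_l ** 2,
    }
    return {name: values[name] for name in feature_names}


def segment_into_minutes(track: PatientTrack, window: float = 60.0,
                         min_final: float | None = None) -> list[PatientTrack]:
    """Partition patient material into consecutive windows of talk time.

    Windows are measured in accumulated *patient* time; turns are split at
    window boundaries. A final partial window shorter than ``min_final``
    (default ``window / 2``) is merged into the previous window. Response
    latencies travel with the window in which their turn starts.
    """
    if min_final is None:
        min_final = window / 2.0
    if track.total_turn_time <= 0:
        raise ValueError("track has no patient material")

    n_lat = len(track.response_latencies)
    lat_for_turn = [None] * len(track.turn_times)
    # latencies correspond to the last n_lat turns with a preceding
    # non-patient turn; reconstruct per-turn alignment conservatively:
    # assign them to turns from the end if counts differ by the first turn.
    offset = len(track.turn_times) - n_lat
    for i in range(n_lat):
        lat_for_turn[offset + i] = track.response_latencies[i]

    windows: list[dict] = []
    cur = {"wavs": [], "times": [], "lats": [], "acc": 0.0}

    def close() -> None:
        nonlocal cur
        if cur["wavs"]:
            windows.append(cur)
        cur = {"wavs": [], "times": [], "lats": [], "acc": 0.0}

    for turn_i, (w, (t0, t1)) in enumerate(
            zip(track.utterance_waveforms, track.turn_times)):
        pos = 0.0
        dur = t1 - t0
        first_piece = True
        while pos < dur - 1e-9:
            room = window - cur["acc"]
            take = min(room, dur - pos)
            piece = w.slice(pos, pos + take)
            cur["wavs"].append(piece)
            cur["times"].append((t0 + pos, t0 + pos + take))
            if first_piece and lat_for_turn[turn_i] is not None:
                cur["lats"].append(lat_for_turn[turn_i])
            first_piece = False
            cur["acc"] += take
            pos += take
            if cur["acc"] >= window - 1e-9:
                close()
    if cur["wavs"]:
        if windows and cur["acc"] < min_final:
            # merge trailing partial window into the previous one
            prev = windows[-1]
            prev["wavs"] += cur["wavs"]
            prev["times"] += cur["times"]
            prev["lats"] += cur["lats"]
        else:
            windows.append(cur)

    return [
        PatientTrack(wi["wavs"], wi["times"], wi["lats"],
                     group_id=track.group_id, label=track.label)
        for wi in windows
    ]
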