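"""Pitch-synchronous voice-quality analysis: F0, jitter, shimmer, HNR/NHR,
voice breaks.

The analysis follows the classical autocorrelation paradigm: each 40 ms
frame is Hann-windowed, its normalized autocorrelation is divided by the
window's own autocorrelation (removing the taper bias), and the strongest
peak in the candidate lag range gives the frame's F0 and a voicing strength
``r`` in [0, 1]. ``r`` estimates the fraction of frame power that is
periodic, so the harmonics-to-noise ratio per frame is
``10 log10(r / (1 - r))`` and the noise-to-harmonics ratio is its linear
reciprocal ``(1 - r) / r``.

Glottal pulse instants are then marked once per period at local waveform
maxima (with parabolic sub-sample refinement); consecutive-cycle period and
amplitude perturbations give jitter(local) and shimmer(local) in percent,
and inter-pulse gaps longer than 16 ms (and out of proportion to the local
period) count as voice breaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft, rfft

from .audio_io import PatientTrack, Waveform

log = logging.getLogger(__name__)

VOICING_THRESHOLD = 0.45
BREAK_MIN_S = 0.016
#: a gap is a break only if it also exceeds this multiple of the local period
BREAK_PERIOD_FACTOR = 1.25

PHONATION_BASES = ("f0", "hnr", "nhr", "shimmer", "jitter", "nvb", "dvb")
PHONATION_FEATURES = tuple(
    f"{base}_{stat}" for base in PHONATION_BASES for stat in ("mean", "std", "var"))


@dataclass
class PitchTrack:
    """Per-frame F0 (Hz; 0 where unvoiced), voicing strength r, frame times."""

    f0: np.ndarray
    strength: np.ndarray
    times: np.ndarray
    voiced: np.ndarray  # bool mask


@dataclass
class PulseTrain:
    """Glottal pulse instants with per-pulse amplitudes.

    ``run_id`` labels the voiced run each pulse belongs to; periods are
    differences between consecutive pulses of the same run.
    """

    pulse_times: np.ndarray
    amplitudes: np.ndarray
    run_id: np.ndarray

    @property
    def periods(self) -> np.ndarray:
        if len(self.pulse_times) < 2:
            return np.empty(0)
        same = self.run_id[1:] == self.run_id[:-1]
        return np.diff(self.pulse_times)[same]


def _parabolic(y0: float, y1: float, y2: float) -> tuple[float, float]:
    """Vertex offset in [-1, 1] and value of the parabola through 3 points."""
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-30:
        return 0.0, y1
    d = 0.5 * (y0 - y2) / denom
    d = float(np.clip(d, -1.0, 1.0))
    return d, y1 - 0.25 * (y0 - y2) * d


def track_pitch(w: Waveform, f0_min: float = 75.0, f0_max: float = 500.0,
                frame: float = 0.040, hop: float = 0.010,
                voicing_threshold: float = VOICING_THRESHOLD,
                silence_db: float = 35.0) -> PitchTrack:
    """Autocorrelation pitch tracking with window-bias correction.

    Frames whose RMS is more than ``silence_db`` below the signal's peak
    frame RMS are unvoiced outright; remaining frames are voiced when the
    corrected autocorrelation peak exceeds ``voicing_threshold``.
    """
    x = w.samples
    fs = w.rate
    flen = int(round(frame * fs))
    hopn = max(1, int(round(hop * fs)))
    if len(x) < flen:
        x = np.pad(x, (0, flen - len(x)))
    n_frames = 1 + (len(x) - flen) // hopn
    idx = np.arange(flen)[None, :] + hopn * np.arange(n_frames)[:, None]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)

    win = np.hanning(flen)
    nfft = int(2 ** np.ceil(np.log2(2 * flen)))
    # window autocorrelation (normalized), for taper-bias correction
    W = rfft(win, nfft)
    acw = irfft(W * np.conj(W), nfft)[:flen]
    acw = acw / acw[0]

    F = rfft(frames * win, nfft, axis=1)
    ac = irfft(F * np.conj(F), nfft, axis=1)[:, :flen]
    power = ac[:, 0].copy()
    power[power <= 0] = 1e-30
    r = ac / power[:, None] / np.maximum(acw, 1e-6)[None, :]

    lag_min = max(2, int(np.floor(fs / f0_max)))
    lag_max = min(flen - 2, int(np.ceil(fs / f0_min)))
    if lag_max <= lag_min:
        raise ValueError("frame too short for the requested F0 range")

    rms = np.sqrt(np.mean(frames ** 2, axis=1))
    peak_rms = rms.max() if len(rms) else 0.0
    loud = rms > peak_rms * 10 ** (-silence_db / 20.0)

    f0 = np.zeros(n_frames)
    strength = np.zeros(n_frames)
    seg = r[:, lag_min:lag_max + 1]
    best = np.argmax(seg, axis=1) + lag_min
    for i in range(n_frames):
        if not loud[i]:
            continue
        lag = best[i]
        # octave-error suppression: a perfectly periodic frame peaks equally
        # at the true lag and its multiples — prefer the half-lag when its
        # correlation is nearly as strong
        while True:
            half = lag // 2
            if half - 1 < lag_min:
                break
            cand = half - 1 + int(np.argmax(r[i, half - 1:half + 2]))
            if r[i, cand] >= 0.95 * r[i, lag]:
                lag = cand
            else:
                break
        d, val = _parabolic(r[i, lag - 1], r[i, lag], r[i, lag + 1])
        strength[i] = min(val, 1.0 - 1e-9)
        if strength[i] >= voicing_threshold:
            f0[i] = fs / (lag + d)
    voiced = f0 > 0
    times = (np.arange(n_frames) * hopn + flen / 2) / fs
    return PitchTrack(f0, strength, times, voiced)


def extract_pulses(w: Waveform, pitch: PitchTrack,
                   amp_gate: float = 0.25) -> PulseTrain:
    """Mark one glottal pulse per period inside voiced runs.

    Within each voiced run the walker anchors on the strongest waveform
    peak of the first period, then steps forward one local period at a
    time, snapping each prediction to the nearest local maximum (parabolic
    sub-sample refinement gives period resolution well below one sample —
    required for jitter in the sub-percent range). Because every step is
    relative to the last *found* pulse, frame-level F0 bias cannot
    accumulate into drift. Predicted positions whose peak falls below
    ``amp_gate`` times the run's median pulse amplitude emit no pulse —
    silent stretches (voice breaks) therefore appear as inter-pulse gaps.
    """
    x = w.samples
    fs = w.rate
    t_all: list[float] = []
    a_all: list[float] = []
    run_all: list[int] = []

    runs = _bool_runs(pitch.voiced)
    hop = pitch.times[1] - pitch.times[0] if len(pitch.times) > 1 else 0.01
    for run_no, (i0, i1) in enumerate(runs):
        t0 = max(0.0, pitch.times[i0] - hop / 2)
        t1 = min(len(x) / fs, pitch.times[i1 - 1] + hop / 2)
        tt = pitch.times[i0:i1]
        f0_run = pitch.f0[i0:i1]
        T_med = 1.0 / np.median(f0_run)
        s0, s1 = int(t0 * fs), int(t1 * fs)
        if s1 - s0 < 3:
            continue
        seg = x[s0:s1]
        ref_amp = float(np.percentile(np.abs(seg), 98))
        if ref_amp <= 0:
            continue
        # anchor: strongest peak within the first 1.5 periods
        n_anchor = min(len(seg), max(3, int(1.5 * T_med * fs)))
        anchor = s0 + int(np.argmax(seg[:n_anchor]))

        pos = float(anchor)
        first = True
        while pos < s1 - 2:
            T_loc = 1.0 / float(np.interp(pos / fs, tt, f0_run))
            # guard against residual octave errors in single frames
            T_loc = float(np.clip(T_loc, 0.7 * T_med, 1.4 * T_med))
            if first:
                center = int(round(pos))
                first = False
            else:
                center = int(round(pos + T_loc * fs))
            hw = max(2, int(0.3 * T_loc * fs))
            lo = max(s0, center - hw)
            hi = min(s1, center + hw + 1)
            if hi - lo < 3 or center >= s1 - 1:
                break
            k = lo + int(np.argmax(x[lo:hi]))
            k = min(max(k, 1), len(x) - 2)
            y0, y1, y2 = x[k - 1], x[k], x[k + 1]
            d, amp = _parabolic(y0, y1, y2)
            if y1 >= amp_gate * ref_amp:
                t_all.append((k + d) / fs)
                a_all.append(abs(amp))
                run_all.append(run_no)
                pos = k + d
            else:
                pos = center  # silent stretch: advance without emitting
    if not t_all:
        return PulseTrain(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    t_arr = np.asarray(t_all)
    a_arr = np.asarray(a_all)
    r_arr = np.asarray(run_all, dtype=int)
    keep = np.concatenate(([True], np.diff(t_arr) > 1e-4))
    return PulseTrain(t_arr[keep], a_arr[keep], r_arr[keep])


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if len(mask) == 0:
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [len(mask)]))
    return [(int(bounds[i]), int(bounds[i + 1]))
            for i in range(len(bounds) - 1) if mask[bounds[i]]]


def _local_perturbation(values: np.ndarray, same_run: np.ndarray) -> float:
    """100 x mean |consecutive difference| / mean value (percent)."""
    if len(values) < 2 or not np.any(same_run):
        warnings.warn("fewer than 2 cycles; perturbation measure set to 0",
                      stacklevel=3)
        return 0.0
    diffs = np.abs(np.diff(values))[same_run]
    if len(diffs) == 0:
        return 0.0
    mean = np.mean(values)
    if mean <= 0:
        return 0.0
    return float(100.0 * np.mean(diffs) / mean)


def jitter_local(p: PulseTrain) -> float:
    """Cycle-to-cycle period perturbation in percent."""
    periods = p.periods
    if len(periods) < 2:
        warnings.warn("fewer than 2 periods; jitter set to 0", stacklevel=2)
        return 0.0
    return float(100.0 * np.mean(np.abs(np.diff(periods))) / np.mean(periods))


def shimmer_local(p: PulseTrain) -> float:
    """Cycle-to-cycle amplitude perturbation in percent."""
    if len(p.amplitudes) < 2:
        warnings.warn("fewer than 2 pulses; shimmer set to 0", stacklevel=2)
        return 0.0
    same = p.run_id[1:] == p.run_id[:-1]
    return _local_perturbation(p.amplitudes, same)


def harmonicity(w: Waveform, pitch: PitchTrack) -> tuple[float, float]:
    """(HNR in dB, NHR as a linear ratio), averaged over voiced frames."""
    r = pitch.strength[pitch.voiced]
    if len(r) == 0:
        warnings.warn("no voiced frames; HNR/NHR set to 0", stacklevel=2)
        return 0.0, 0.0
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    hnr_frames = 10.0 * np.log10(r / (1.0 - r))
    nhr_frames = (1.0 - r) / r
    return float(np.mean(hnr_frames)), float(np.mean(nhr_frames))


def voice_breaks(p: PulseTrain, utterance_duration: float,
                 break_min: float = BREAK_MIN_S) -> tuple[int, float]:
    """Count and degree of voice breaks in one utterance.

    A break is an inter-pulse gap longer than ``break_min`` (16 ms) that
    also exceeds ``BREAK_PERIOD_FACTOR`` times the local median period (so
    normal low-F0 cycles are not flagged). Within-turn silent pauses leave
    long inter-pulse gaps and therefore count as voicing interruptions, as
    in standard voice-report practice. Degree is total break time over the
    utterance duration.
    """
    if len(p.pulse_times) < 2 or utterance_duration <= 0:
        return 0, 0.0
    gaps = np.diff(p.pulse_times)
    periods = p.periods
    med = np.median(periods) if len(periods) else np.inf
    is_break = (gaps > break_min) & (gaps > BREAK_PERIOD_FACTOR * med)
    count = int(np.sum(is_break))
    degree = float(np.sum(gaps[is_break]) / utterance_duration)
    return count, min(degree, 1.0)


def analyse_utterance(w: Waveform, f0_min: float = 75.0, f0_max: float = 500.0,
                      voicing_threshold: float = VOICING_THRESHOLD,
                      break_min: float = BREAK_MIN_S) -> dict[str, float] | None:
    """Per-utterance base measures; None if too short/unvoiced to analyse."""
    pitch = track_pitch(w, f0_min=f0_min, f0_max=f0_max,
                        voicing_threshold=voicing_threshold)
    if not np.any(pitch.voiced):
        return None
    f0_mean = float(np.mean(pitch.f0[pitch.voiced]))
    if w.duration < 3.0 / max(f0_mean, f0_min):
        log.info("utterance shorter than 3 periods; skipped for phonation")
        return None
    pulses = extract_pulses(w, pitch)
    hnr, nhr = harmonicity(w, pitch)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        jit = jitter_local(pulses)
        shim = shimmer_local(pulses)
    nvb, dvb = voice_breaks(pulses, w.duration, break_min=break_min)
    return {"f0": f0_mean, "hnr": hnr, "nhr": nhr, "shimmer": shim,
            "jitter": jit, "nvb": float(nvb), "dvb": dvb}


def phonation_features(track: PatientTrack, **kwargs) -> dict[str, float]:
    """21 phonation features: mean/STD/variance of each base measure across
    the patient's utterances (population statistics; one utterance gives
    STD = variance = 0)."""
    rows = []
    for w in track.utterance_waveforms:
        m = analyse_utterance(w, **kwargs)
        if m is not None:
            rows.append(m)
    out: dict[str, float] = {}
    for base in PHONATION_BASES:
        vals = np.array([r[base] for r in rows]) if rows else np.empty(0)
        if len(vals) == 0:
            mean = std = 0.0
            warnings.warn("no analysable utterances; phonation features 0",
                          stacklevel=2)
        else:
            mean, std = float(np.mean(vals)), float(np.std(vals))
        out[f"{base}_mean"] = mean
        out[f"{base}_std"] = std
        out[f"{base}_var"] = std ** 2
    return out
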