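"""Audio loading, noise gating, and patient-turn isolation.

Clinic conversations arrive as mono WAV files plus a speaker-turn annotation
(start, end, speaker per turn). Everything downstream analyses only the
patient's own speech material, so this module canonicalizes the audio
(mono, 16 kHz, amplitude in [-1, 1]), optionally applies a spectral noise
gate, and slices out the patient turns together with their response
latencies (the gap between the end of the preceding non-patient turn and
the start of each patient turn).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly, stft, istft

CANONICAL_RATE = 16_000

SPEAKER_PATIENT = "patient"


@dataclass
class Waveform:
    """Mono audio signal with its sample rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform must be mono (1-D samples)")
        if self.rate <= 0:
            raise ValueError("Waveform rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def slice(self, start: float, end: float) -> "Waveform":
        """Sub-waveform between two times in seconds."""
        i0 = int(round(start * self.rate))
        i1 = int(round(end * self.rate))
        return Waveform(self.samples[i0:i1].copy(), self.rate)


@dataclass
class TurnAnnotation:
    """Ordered, non-overlapping speaker turns: (start_s, end_s, speaker)."""

    turns: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        prev_end = 0.0
        for start, end, _ in self.turns:
            if not (0.0 <= start < end):
                raise ValueError(f"invalid turn interval ({start}, {end})")
            if start < prev_end - 1e-9:
                raise ValueError("turns overlap or are unsorted")
            prev_end = end
        if not any(s == SPEAKER_PATIENT for _, _, s in self.turns):
            raise ValueError("annotation contains no patient turn")

    def patient_turns(self) -> list[tuple[float, float]]:
        return [(a, b) for a, b, s in self.turns if s == SPEAKER_PATIENT]


@dataclass
class PatientTrack:
    """Patient-only material: one waveform per patient turn.

    ``response_latencies`` holds, for each patient turn that has a preceding
    non-patient turn, the silent gap between them (clamped at zero for
    overlapping annotations).
    """

    utterance_waveforms: list[Waveform]
    turn_times: list[tuple[float, float]]
    response_latencies: list[float]
    group_id: str | None = None
    label: str | None = None

    @property
    def total_turn_time(self) -> float:
        return float(sum(e - s for s, e in self.turn_times))

    @property
    def rate(self) -> int:
        return self.utterance_waveforms[0].rate


def load_audio(path: str | Path, target_rate: int = CANONICAL_RATE) -> Waveform:
    """Read a PCM WAV file, average to mono, resample, scale to [-1, 1]."""
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise ValueError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty WAV file {path}")
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        # symmetric scale so int16 k -> k/32767 -> k round-trips bit-exactly
        data = np.clip(data / float(np.iinfo(data.dtype).max), -1.0, 1.0)
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    peak = np.max(np.abs(data))
    if peak > 1.0:
        data = data / peak
    w = Waveform(data, int(rate))
    if w.rate != target_rate:
        w = resample(w, target_rate)
    return w


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Polyphase resampling to ``target_rate`` (anti-aliased)."""
    if w.rate == target_rate:
        return w
    from math import gcd

    g = gcd(w.rate, target_rate)
    up, down = target_rate // g, w.rate // g
    y = resample_poly(w.samples, up, down)
    return Waveform(y, target_rate)


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write 16-bit PCM; amplitudes outside [-1, 1] are clipped."""
    x = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(Path(path), w.rate, (x * 32767.0).round().astype(np.int16))


def spectral_noise_gate(
    w: Waveform,
    noise_profile: Waveform | tuple[float, float],
    reduction_db: float = 12.0,
    n_fft: int = 2048,
    threshold_sd: float = 1.5,
    smooth_frames: int = 3,
) -> Waveform:
    """Attenuate time-frequency bins that fall below a noise-profile threshold.

    Per frequency bin the gate threshold is (noise mean + ``threshold_sd`` x
    noise SD) of the short-time magnitude, estimated from ``noise_profile``
    (a noise-only waveform, or a (start, end) time range into ``w``). Bins
    below threshold are attenuated by ``reduction_db``; the gain mask is
    smoothed over ``smooth_frames`` frames to avoid musical noise.
    """
    if isinstance(noise_profile, tuple):
        noise_profile = w.slice(*noise_profile)
    if noise_profile.rate != w.rate:
        raise ValueError("noise profile rate differs from signal rate")
    if len(noise_profile.samples) < n_fft:
        raise ValueError("noise profile shorter than one analysis frame")
    if reduction_db <= 0:
        return Waveform(w.samples.copy(), w.rate)

    noverlap = n_fft // 2
    _, _, Zn = stft(noise_profile.samples, fs=w.rate, nperseg=n_fft,
                    noverlap=noverlap)
    mag_n = np.abs(Zn)
    thresh = mag_n.mean(axis=1) + threshold_sd * mag_n.std(axis=1)

    _, _, Z = stft(w.samples, fs=w.rate, nperseg=n_fft, noverlap=noverlap)
    gain_db = np.where(np.abs(Z) < thresh[:, None], -reduction_db, 0.0)
    if smooth_frames > 1:
        # smooth in the log domain so boundary frames stay well attenuated
        kernel = np.ones(smooth_frames) / smooth_frames
        gain_db = np.apply_along_axis(
            lambda g: np.convolve(g, kernel, mode="same"), 1, gain_db)
    gain = 10.0 ** (gain_db / 20.0)
    _, y = istft(Z * gain, fs=w.rate, nperseg=n_fft, noverlap=noverlap)
    y = y[: len(w.samples)]
    if len(y) < len(w.samples):
        y = np.pad(y, (0, len(w.samples) - len(y)))
    return Waveform(y, w.rate)


def extract_patient_track(w: Waveform, ann: TurnAnnotation) -> PatientTrack:
    """Isolate patient turns and compute per-turn response latencies."""
    dur = w.duration
    for start, end, _ in ann.turns:
        if end > dur + 1e-6:
            raise ValueError(
                f"annotation time {end:.3f}s beyond audio end {dur:.3f}s")
    utterances: list[Waveform] = []
    times: list[tuple[float, float]] = []
    latencies: list[float] = []
    prev_nonpatient_end: float | None = None
    for start, end, speaker in ann.turns:
        if speaker == SPEAKER_PATIENT:
            utterances.append(w.slice(start, end))
            times.append((start, end))
            if prev_nonpatient_end is not None:
                latencies.append(max(0.0, start - prev_nonpatient_end))
        else:
            prev_nonpatient_end = end
    if not utterances:
        raise ValueError("annotation contains no patient turn")
    return PatientTrack(utterances, times, latencies)


# ---------------------------------------------------------------------------
# Annotation readers: TSV ("start<TAB>end<TAB>speaker") and Praat TextGrid
# interval tiers.
# ---------------------------------------------------------------------------

def read_annotation_tsv(path: str | Path) -> TurnAnnotation:
    turns = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed annotation line: {line!r}")
        try:
            start, end = float(parts[0]), float(parts[1])
        except ValueError:
            continue  # header row
        turns.append((start, end, parts[2].strip().lower()))
    return TurnAnnotation(turns)


def write_annotation_tsv(path: str | Path, ann: TurnAnnotation) -> None:
    lines = ["start\tend\tspeaker"]
    lines += [f"{s:.3f}\t{e:.3f}\t{sp}" for s, e, sp in ann.turns]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_TG_FLOAT = re.compile(r"(?:xmin|xmax)\s*=\s*([0-9.eE+-]+)")
_TG_TEXT = re.compile(r'text\s*=\s*"(.*)"')


def read_annotation_textgrid(path: str | Path, tier: str | None = None) -> TurnAnnotation:
    """Read speaker turns from a Praat TextGrid interval tier.

    Interval labels are taken as speaker names; empty-label intervals are
    skipped. If ``tier`` is given, only the tier with that name is read;
    otherwise intervals from the first interval tier are used.
    """
    text = Path(path).read_text(encoding="utf-8")
    # split into tiers ("item [n]:" blocks); fall back to whole file
    blocks = re.split(r"item\s*\[\d+\]\s*:", text)
    chosen = None
    for block in blocks[1:] or [text]:
        m = re.search(r'name\s*=\s*"(.*)"', block)
        if "IntervalTier" not in block:
            continue
        if tier is None or (m and m.group(1) == tier):
            chosen = block
            break
    if chosen is None:
        raise ValueError(f"no matching interval tier in {path}")
    turns = []
    for interval in re.split(r"intervals\s*\[\d+\]\s*:", chosen)[1:]:
        times = _TG_FLOAT.findall(interval)
        label = _TG_TEXT.search(interval)
        if len(times) >= 2 and label and label.group(1).strip():
            turns.append((float(times[0]), float(times[1]),
                          label.group(1).strip().lower()))
    return TurnAnnotation(turns)


def read_annotation(path: str | Path) -> TurnAnnotation:
    path = Path(path)
    if path.suffix.lower() == ".textgrid":
        return read_annotation_textgrid(path)
    return read_annotation_tsv(path)
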