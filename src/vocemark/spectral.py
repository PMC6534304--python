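"""Frame-level spectral analysis and the duration-weighted spectral block.

Per 25 ms frame (10 ms hop) the signal is pre-emphasized, Hamming-windowed
and transformed to a power spectrum; 26 triangular mel filters spanning
0-8 kHz yield

* ``fbank`` — the 26 log filter energies,
* ``mfcc``  — the first 13 DCT-II coefficients of the fbank vector
  (c1..c13; c0, a pure gain term, is excluded),
* ``ssc``   — each filter's energy as a share of the total filter energy
  (the normalized-subband-energy variant; entries over all 26 filters sum
  to exactly 1, the first 13 are retained).

Per utterance the frame means are divided by the utterance duration, giving
averaged weighted spectral coefficients (AWSC, units 1/s): slower, sparser
speech shrinks the AWSC magnitude, deliberately folding response timing
into the spectral features. Five descriptive statistics of the scalarized
AWSC across utterances per subgroup give the 15 spectral features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft

from .audio_io import PatientTrack, Waveform

PREEMPHASIS = 0.97
LOG_FLOOR = 1e-10

SPECTRAL_GROUPS = ("mfcc", "fbank", "ssc")
SPECTRAL_STATS = ("mean", "std", "min", "max", "var")
SPECTRAL_FEATURES = tuple(
    f"{g}_{s}" for g in SPECTRAL_GROUPS for s in SPECTRAL_STATS)


@dataclass
class FrameSpectra:
    mfcc: np.ndarray   # (n_frames, n_keep)
    fbank: np.ndarray  # (n_frames, n_mels)
    ssc: np.ndarray    # (n_frames, n_keep)
    frame_times: np.ndarray


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, rate: int,
                   f_lo: float = 0.0, f_hi: float | None = None) -> np.ndarray:
    """(n_mels, n_fft//2 + 1) triangular filters on the mel scale."""
    if f_hi is None:
        f_hi = rate / 2.0
    mel_pts = np.linspace(hz_to_mel(f_lo), hz_to_mel(f_hi), n_mels + 2)
    hz_pts = np.asarray(mel_to_hz(mel_pts))
    bins = np.floor((n_fft + 1) * hz_pts / rate).astype(int)
    fb = np.zeros((n_mels, n_fft // 2 + 1))
    for j in range(n_mels):
        lo, ctr, hi = bins[j], bins[j + 1], bins[j + 2]
        for k in range(lo, ctr):
            if ctr > lo:
                fb[j, k] = (k - lo) / (ctr - lo)
        for k in range(ctr, hi):
            if hi > ctr:
                fb[j, k] = (hi - k) / (hi - ctr)
    return fb


def frame_spectra(w: Waveform, frame: float = 0.025, hop: float = 0.010,
                  n_fft: int | None = None, n_mels: int = 26,
                  n_keep: int = 13,
                  preemphasis: float = PREEMPHASIS) -> FrameSpectra:
    """Compute MFCC / log-mel filterbank / subband-energy-share frames."""
    fs = w.rate
    flen = int(round(frame * fs))
    hopn = max(1, int(round(hop * fs)))
    if len(w.samples) < flen:
        raise ValueError("waveform shorter than one analysis frame")
    if n_fft is None:
        n_fft = int(2 ** np.ceil(np.log2(flen)))
    x = np.append(w.samples[0], w.samples[1:] - preemphasis * w.samples[:-1])
    n_frames = 1 + (len(x) - flen) // hopn
    idx = np.arange(flen)[None, :] + hopn * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hamming(flen)[None, :]
    power = np.abs(rfft(frames, n_fft, axis=1)) ** 2

    fb = mel_filterbank(n_mels, n_fft, fs)
    energies = power @ fb.T  # (n_frames, n_mels)
    fbank = np.log(np.maximum(energies, LOG_FLOOR))
    cep = dct(fbank, type=2, norm="ortho", axis=1)
    mfcc = cep[:, 1:n_keep + 1]
    total = np.maximum(energies.sum(axis=1, keepdims=True), LOG_FLOOR)
    ssc_full = energies / total
    ssc = ssc_full[:, :n_keep]
    times = (np.arange(n_frames) * hopn + flen / 2) / fs
    return FrameSpectra(mfcc, fbank, ssc, times)


def awsc(fs: FrameSpectra, utterance_duration: float) -> dict[str, np.ndarray]:
    """Frame-mean coefficient vectors divided by utterance duration (1/s)."""
    if utterance_duration <= 0:
        raise ValueError("utterance duration must be positive")
    return {
        "mfcc": fs.mfcc.mean(axis=0) / utterance_duration,
        "fbank": fs.fbank.mean(axis=0) / utterance_duration,
        "ssc": fs.ssc.mean(axis=0) / utterance_duration,
    }


def spectral_features(awsc_list: list[dict[str, np.ndarray]]) -> dict[str, float]:
    """15 descriptive features across utterances.

    Each utterance's AWSC subgroup vector is first scalarized (mean over
    its coefficients); the five descriptive statistics are then taken
    across utterances per subgroup (population STD/variance).
    """
    if not awsc_list:
        raise ValueError("need at least one utterance")
    out: dict[str, float] = {}
    for g in SPECTRAL_GROUPS:
        scalars = np.array([float(np.mean(a[g])) for a in awsc_list])
        std = float(np.std(scalars))
        out[f"{g}_mean"] = float(np.mean(scalars))
        out[f"{g}_std"] = std
        out[f"{g}_min"] = float(np.min(scalars))
        out[f"{g}_max"] = float(np.max(scalars))
        out[f"{g}_var"] = std ** 2
    return out


def spectral_features_for_track(track: PatientTrack, **kwargs) -> dict[str, float]:
    """Spectral feature block for a patient track (one AWSC per turn)."""
    alist = []
    for w in track.utterance_waveforms:
        if w.duration <= 0:
            continue
        flen = kwargs.get("frame", 0.025)
        if w.duration < flen:
            continue
        fs_ = frame_spectra(w, **kwargs)
        alist.append(awsc(fs_, w.duration))
    if not alist:
        raise ValueError("no utterance long enough for spectral analysis")
    return spectral_features(alist)
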