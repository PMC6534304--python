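"""Pitch tracking, jitter/shimmer, harmonicity, voice breaks."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import FS, tone
from vocemark.audio_io import PatientTrack, Waveform
from vocemark.phonation import (PHONATION_FEATURES, PitchTrack, PulseTrain,
                                extract_pulses, harmonicity, jitter_local,
                                phonation_features, shimmer_local, track_pitch,
                                voice_breaks)
from vocemark.synthgen import VoiceSpec, synthesize_voice


def pulses_from_periods(periods, amplitudes=None):
    times = np.concatenate([[0.1], 0.1 + np.cumsum(periods)])
    amps = np.asarray(amplitudes) if amplitudes is not None \
        else np.ones(len(times))
    return PulseTrain(times, amps, np.zeros(len(times), dtype=int))


class TestTrackPitch:
    def test_pure_sine_is_voiced_at_200hz(self):
        w = Waveform(tone(200, 1.0), FS)
        pt = track_pitch(w)
        assert pt.voiced.mean() > 0.95
        assert np.abs(np.median(pt.f0[pt.voiced]) - 200.0) < 1.0

    def test_white_noise_mostly_unvoiced(self, rng):
        w = Waveform(0.3 * rng.normal(size=FS), FS)
        pt = track_pitch(w)
        assert pt.voiced.mean() < 0.10

    def test_silence_fully_unvoiced(self):
        w = Waveform(np.zeros(FS), FS)
        pt = track_pitch(w)
        assert not pt.voiced.any()


class TestExtractPulses:
    def test_sine_pulse_count_and_period(self):
        w = Waveform(tone(200, 0.5), FS)
        p = extract_pulses(w, track_pitch(w))
        assert 90 <= len(p.pulse_times) <= 100   # ~100 cycles minus edges
        assert np.allclose(p.periods, 0.005, atol=1e-4)

    def test_synthetic_100hz_pulse_train(self):
        spec = VoiceSpec(f0=100, jitter_sigma=0.0, shimmer_sigma=0.0,
                         target_hnr=np.inf, break_rate=0.0)
        w, truth = synthesize_voice(spec, 1.0, seed=3)
        p = extract_pulses(w, track_pitch(w))
        assert abs(len(p.pulse_times) - len(truth["pulse_times"])) <= 5
        assert np.allclose(np.median(p.periods), 0.010, atol=2e-4)

    def test_silence_gives_empty_train(self):
        w = Waveform(np.zeros(FS), FS)
        p = extract_pulses(w, track_pitch(w))
        assert len(p.pulse_times) == 0


class TestPerturbationMeasures:
    def test_constant_periods_zero_jitter(self):
        p = pulses_from_periods([0.01] * 50)
        assert jitter_local(p) == pytest.approx(0.0, abs=1e-10)

    def test_alternating_periods_formula(self):
        p = pulses_from_periods([0.010, 0.0102] * 25)
        assert jitter_local(p) == pytest.approx(100 * 0.0002 / 0.0101,
                                                rel=1e-6)

    def test_alternating_amplitudes_formula(self):
        p = pulses_from_periods([0.01] * 49, amplitudes=[1.0, 0.9] * 25)
        assert shimmer_local(p) == pytest.approx(100 * 0.1 / 0.95, rel=1e-6)

    def test_too_few_periods_warns_and_zeroes(self):
        p = PulseTrain(np.array([0.1]), np.array([1.0]),
                       np.array([0], dtype=int))
        with pytest.warns(UserWarning):
            assert jitter_local(p) == 0.0

    def test_jitter_amplitude_invariance_and_shift(self):
        w1, _ = synthesize_voice(VoiceSpec(f0=180, jitter_sigma=0.01,
                                           shimmer_sigma=0.0,
                                           target_hnr=np.inf, break_rate=0.0),
                                 1.0, seed=9)
        w2 = Waveform(0.2 * w1.samples, FS)
        j1 = jitter_local(extract_pulses(w1, track_pitch(w1)))
        j2 = jitter_local(extract_pulses(w2, track_pitch(w2)))
        assert j1 == pytest.approx(j2, rel=0.05)

    def test_jitter_tracks_imposed_perturbation_rank(self):
        grid = np.linspace(0.002, 0.03, 8)
        meas = []
        for js in grid:
            spec = VoiceSpec(f0=200, jitter_sigma=float(js), shimmer_sigma=0.0,
                             target_hnr=np.inf, break_rate=0.0)
            w, _ = synthesize_voice(spec, 1.5, seed=21)
            meas.append(jitter_local(extract_pulses(w, track_pitch(w))))
        assert spearmanr(grid, meas).statistic >= 0.95


class TestHarmonicity:
    def test_half_strength_frame_is_zero_db(self):
        pt = PitchTrack(np.array([200.0]), np.array([0.5]),
                        np.array([0.02]), np.array([True]))
        hnr, nhr = harmonicity(Waveform(tone(200, 0.1), FS), pt)
        assert hnr == pytest.approx(0.0, abs=1e-9)
        assert nhr == pytest.approx(1.0, abs=1e-9)

    def test_frame_level_reciprocal_identity(self, rng):
        r = rng.uniform(0.05, 0.95, 20)
        pt = PitchTrack(np.full(20, 200.0), r, np.arange(20) * 0.01,
                        np.ones(20, dtype=bool))
        w = Waveform(tone(200, 0.3), FS)
        for ri in r:
            single = PitchTrack(np.array([200.0]), np.array([ri]),
                                np.array([0.0]), np.array([True]))
            hnr, nhr = harmonicity(w, single)
            assert nhr == pytest.approx(10 ** (-hnr / 10), rel=1e-9)

    def test_pure_sine_hnr_exceeds_25db(self):
        w = Waveform(tone(200, 1.0), FS)
        hnr, _ = harmonicity(w, track_pitch(w))
        assert hnr >= 25.0

    def test_hnr_tracks_snr_and_decreases_with_noise(self, rng):
        sig = tone(200, 1.0)
        sig_p = np.mean(sig ** 2)
        prev = np.inf
        for snr in (30, 20, 10, 5, 0):
            noise = rng.normal(size=len(sig))
            noise *= np.sqrt(sig_p / np.mean(noise ** 2) / 10 ** (snr / 10))
            w = Waveform(sig + noise, FS)
            hnr, _ = harmonicity(w, track_pitch(w))
            assert abs(hnr - snr) <= 3.0
            assert hnr < prev
            prev = hnr

    def test_unvoiced_input_warns(self):
        w = Waveform(np.zeros(FS), FS)
        with pytest.warns(UserWarning):
            assert harmonicity(w, track_pitch(w)) == (0.0, 0.0)


class TestVoiceBreaks:
    def test_inserted_20ms_gap_counts_once(self):
        periods = [0.01] * 50 + [0.020] + [0.01] * 50
        p = pulses_from_periods(periods)
        count, _ = voice_breaks(p, 1.2)
        assert count == 1

    def test_no_long_gaps_no_breaks(self):
        p = pulses_from_periods([0.01] * 100)
        assert voice_breaks(p, 1.0) == (0, 0.0)

    def test_three_gaps_degree_arithmetic(self):
        periods = ([0.01] * 30 + [0.1] + [0.01] * 30 + [0.2]
                   + [0.01] * 30 + [0.3] + [0.01] * 30)
        p = pulses_from_periods(periods)
        count, degree = voice_breaks(p, 10.0)
        assert count == 3
        assert degree == pytest.approx(0.06, rel=1e-6)

    def test_degree_bounded_by_one(self):
        p = pulses_from_periods([0.01, 5.0, 0.01])
        _, degree = voice_breaks(p, 1.0)
        assert 0.0 <= degree <= 1.0

    def test_generator_breaks_recovered(self):
        spec = VoiceSpec(f0=200, jitter_sigma=0.005, shimmer_sigma=0.03,
                         target_hnr=25, break_rate=0.3)
        w, truth = synthesize_voice(spec, 10.0, seed=5)
        p = extract_pulses(w, track_pitch(w))
        count, degree = voice_breaks(p, 10.0)
        assert count == len(truth["breaks"])
        true_degree = sum(d for _, d in truth["breaks"]) / 10.0
        assert degree == pytest.approx(true_degree, abs=0.01)


class TestPhonationFeatures:
    def _track(self, f0s, duration=1.0):
        wavs = []
        for i, f0 in enumerate(f0s):
            spec = VoiceSpec(f0=f0, jitter_sigma=0.0, shimmer_sigma=0.0,
                             target_hnr=np.inf, break_rate=0.0)
            w, _ = synthesize_voice(spec, duration, seed=40 + i)
            wavs.append(w)
        times = [(2.0 * i, 2.0 * i + duration) for i in range(len(wavs))]
        return PatientTrack(wavs, times, [])

    def test_has_21_fields_with_var_identity(self):
        f = phonation_features(self._track([200.0]))
        assert len(f) == 21 and tuple(f) == PHONATION_FEATURES
        for base in ("f0", "hnr", "jitter"):
            assert f[f"{base}_var"] == pytest.approx(
                f[f"{base}_std"] ** 2, abs=1e-9)

    def test_identical_utterances_zero_std(self):
        f = phonation_features(self._track([210.0, 210.0]))
        assert f["f0_std"] == pytest.approx(0.0, abs=0.5)

    def test_two_utterance_population_statistics(self):
        f = phonation_features(self._track([180.0, 220.0]))
        assert f["f0_mean"] == pytest.approx(200.0, abs=2.0)
        assert f["f0_std"] == pytest.approx(20.0, abs=2.0)
        assert f["f0_var"] == pytest.approx(f["f0_std"] ** 2, abs=1e-9)
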