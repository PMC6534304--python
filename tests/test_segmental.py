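"""Voice activity detection, pause/speech statistics, talk-time windowing."""

import numpy as np
import pytest

from conftest import FS, silence, tone, track_from_layout
from vocemark.audio_io import PatientTrack, Waveform
from vocemark.segmental import (HOP_S, SEGMENTAL_FEATURES, SegmentSet,
                                detect_segments, segment_into_minutes,
                                segmental_features)

HOP = HOP_S


class TestDetectSegments:
    def test_tone_silence_tone_layout(self):
        track, speech, pauses = track_from_layout(
            [("speech", 2.0), ("pause", 0.4), ("speech", 2.6)])
        seg = detect_segments(track)
        assert len(seg.pauses) == 1 and len(seg.speech_segments) == 2
        for (da, db), (ta, tb) in zip(seg.pauses, pauses):
            assert abs(da - ta) <= HOP and abs(db - tb) <= HOP
        for (da, db), (ta, tb) in zip(seg.speech_segments, speech):
            assert abs(da - ta) <= HOP and abs(db - tb) <= HOP

    def test_gap_below_pause_min_merges_speech(self):
        track, _, _ = track_from_layout(
            [("speech", 1.0), ("pause", 0.2), ("speech", 1.0)])
        seg = detect_segments(track)
        assert len(seg.pauses) == 0
        assert len(seg.speech_segments) == 1

    def test_short_burst_is_not_speech(self):
        track, _, _ = track_from_layout(
            [("pause", 1.0), ("speech", 0.4), ("pause", 1.0)])
        seg = detect_segments(track)
        assert len(seg.speech_segments) == 0

    @pytest.mark.parametrize("dur,expect_pause", [(0.24, 0), (0.27, 1)])
    def test_pause_threshold_boundary(self, dur, expect_pause):
        track, _, _ = track_from_layout(
            [("speech", 1.0), ("pause", dur), ("speech", 1.0)])
        assert len(detect_segments(track).pauses) == expect_pause

    @pytest.mark.parametrize("dur,expect_speech", [(0.48, 0), (0.52, 1)])
    def test_speech_threshold_boundary(self, dur, expect_speech):
        track, _, _ = track_from_layout(
            [("pause", 1.0), ("speech", dur), ("pause", 1.0)])
        assert len(detect_segments(track).speech_segments) == expect_speech

    def test_amplitude_scaling_invariance(self):
        layout = [("speech", 1.2), ("pause", 0.5), ("speech", 0.9)]
        track, _, _ = track_from_layout(layout)
        seg1 = detect_segments(track)
        scaled = PatientTrack(
            [Waveform(0.05 * w.samples, w.rate)
             for w in track.utterance_waveforms],
            track.turn_times, track.response_latencies)
        seg2 = detect_segments(scaled)
        assert seg1.pauses == seg2.pauses
        assert seg1.speech_segments == seg2.speech_segments

    def test_silence_padding_shifts_intervals(self):
        layout = [("speech", 1.2), ("pause", 0.5), ("speech", 0.9)]
        track, _, _ = track_from_layout(layout)
        seg1 = detect_segments(track)
        w = track.utterance_waveforms[0]
        padded = PatientTrack(
            [Waveform(np.concatenate([silence(1.0), w.samples]), w.rate)],
            [(0.0, w.duration + 1.0)], [])
        seg2 = detect_segments(padded)
        assert len(seg2.pauses) <= len(seg1.pauses) + 1
        shifted = [p for p in seg2.pauses if p[0] > 0.5]
        for (da, db), (ea, eb) in zip(shifted, seg1.pauses):
            assert abs(da - (ea + 1.0)) <= 2 * HOP
            assert abs(db - (eb + 1.0)) <= 2 * HOP

    def test_pause_and_speech_time_bounded_by_total(self, rng):
        layout = []
        for _ in range(8):
            layout.append(("speech", rng.uniform(0.6, 2.0)))
            layout.append(("pause", rng.uniform(0.3, 1.0)))
        track, _, _ = track_from_layout(layout)
        seg = detect_segments(track)
        assert (seg.pause_durations.sum() + seg.speech_durations.sum()
                <= track.total_turn_time + 1e-9)

    def test_random_layout_matches_brute_force(self, rng):
        # brute-force oracle: statistics straight from the generating layout
        for _ in range(3):
            layout = []
            for i in range(10):
                layout.append(("speech", rng.uniform(0.55, 2.5)))
                if i < 9:
                    layout.append(("pause", rng.uniform(0.3, 1.2)))
            track, speech, pauses = track_from_layout(layout)
            seg = detect_segments(track)
            assert len(seg.pauses) == len(pauses)
            assert len(seg.speech_segments) == len(speech)
            true_p = np.array([b - a for a, b in pauses])
            true_s = np.array([b - a for a, b in speech])
            # one hop per boundary -> two hops per duration
            assert np.max(np.abs(np.sort(seg.pause_durations)
                                 - np.sort(true_p))) <= 2 * HOP
            assert np.max(np.abs(np.sort(seg.speech_durations)
                                 - np.sort(true_s))) <= 2 * HOP


class TestSegmentalFeatures:
    def _dummy_track(self, total=10.0, latencies=(0.5, 1.5)):
        w = Waveform(np.zeros(int(total * FS)), FS)
        return PatientTrack([w], [(0.0, total)], list(latencies))

    def test_stated_arithmetic_example(self):
        seg = SegmentSet(pauses=[(0.0, 0.3), (1.0, 1.5)],
                         speech_segments=[(2.0, 3.0), (3.5, 5.5), (6.0, 6.6)],
                         total_time=10.0)
        track = self._dummy_track(10.0)
        f = segmental_features(seg, track)
        assert f["max_pause"] == pytest.approx(0.5)
        assert f["mean_pause"] == pytest.approx(0.4)
        assert f["ratio_total_pause_total"] == pytest.approx(0.08)
        assert f["ratio_max_speech_max_pause"] == pytest.approx(4.0)
        assert f["mean_long_speech"] == pytest.approx(1.5)  # {1.0, 2.0}
        assert f["ratio_pause_count_total"] == pytest.approx(0.2)
        assert f["mean_response_time"] == pytest.approx(1.0)
        assert f["var_long_speech"] == pytest.approx(
            f["std_long_speech"] ** 2, abs=1e-9)

    def test_default_schema_has_15_names(self):
        seg = SegmentSet([], [(0.0, 1.0)], 1.0)
        f = segmental_features(seg, self._dummy_track(1.0, ()))
        assert len(f) == 15
        assert tuple(f) == SEGMENTAL_FEATURES

    def test_no_pauses_degenerates_to_zero_with_warning(self):
        seg = SegmentSet([], [(0.0, 2.0)], 5.0)
        with pytest.warns(UserWarning, match="no pauses"):
            f = segmental_features(seg, self._dummy_track(5.0))
        assert f["std_pause"] == 0.0
        assert f["ratio_max_speech_max_pause"] == 0.0

    def test_ratios_bounded_when_nested(self, rng):
        starts = np.cumsum(rng.uniform(0.3, 1.0, 20))
        pauses, speech = [], []
        for i in range(0, 18, 2):
            speech.append((starts[i], starts[i + 1]))
            pauses.append((starts[i + 1], starts[i + 1] + 0.26))
        total = float(starts[-1] + 1.0)
        seg = SegmentSet(pauses, speech, total)
        f = segmental_features(seg, self._dummy_track(total))
        for key in ("ratio_max_pause_total", "ratio_total_pause_total",
                    "ratio_total_speech_total"):
            assert 0.0 <= f[key] <= 1.0


class TestSegmentIntoMinutes:
    def _track_seconds(self, secs):
        w = Waveform(tone(200, secs), FS)
        return PatientTrack([w], [(0.0, secs)], [0.7], group_id="p1",
                            label="ND")

    def test_150s_gives_60_60_30(self):
        wins = segment_into_minutes(self._track_seconds(150.0), window=60.0)
        assert [round(t.total_turn_time) for t in wins] == [60, 60, 30]

    def test_59s_single_window(self):
        wins = segment_into_minutes(self._track_seconds(59.0), window=60.0)
        assert len(wins) == 1
        assert wins[0].total_turn_time == pytest.approx(59.0, abs=1e-6)

    def test_short_tail_merges_into_previous(self):
        wins = segment_into_minutes(self._track_seconds(75.0), window=60.0)
        assert len(wins) == 1   # 15 s tail < 30 s merges
        assert wins[0].total_turn_time == pytest.approx(75.0, abs=1e-6)

    def test_group_label_carried(self):
        wins = segment_into_minutes(self._track_seconds(130.0), window=60.0)
        assert all(t.group_id == "p1" and t.label == "ND" for t in wins)

    def test_windows_partition_talk_time(self):
        track = self._track_seconds(200.0)
        wins = segment_into_minutes(track, window=60.0)
        assert sum(t.total_turn_time for t in wins) == pytest.approx(
            track.total_turn_time, abs=1e-6)
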