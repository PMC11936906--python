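"""Playback alignment, call detection, window assignment and tabulation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from finchcall import (
    CallEvent,
    ScoringConfig,
    align_playback,
    assign_windows,
    dependent_variables,
    detect_calls,
    synth_recording,
    tabulate_counts,
)
from finchcall.core import concatenate, silence
from finchcall.designs import SESSION_PER_CONDITION, single_condition_playlist
from finchcall.scoring import scheduled_cells

RATE = 22_050
CFG = ScoringConfig(pre_window=1.0, post_window=1.0)


@pytest.fixture(scope="module")
def playlist(template):
    preset = dataclasses.replace(SESSION_PER_CONDITION, n_songs_per_playback=3, inter_song_silence_s=2.0)
    return single_condition_playlist(
        template, preset, "FIXED", lead_in=1.0, lead_out=1.0
    )


class TestAlignPlayback:
    def test_self_alignment_with_delay(self, playlist):
        wave, _ = playlist
        delayed = concatenate([silence(3.0, RATE), wave])
        rec = synth_recording(delayed, -30.0, [], noise_level=-70.0, seed=0)
        lag, score = align_playback(rec, wave)
        assert abs(lag - 3.0) <= 0.005
        assert score > 0.9

    def test_alignment_robust_to_loud_calls(self, playlist):
        wave, _ = playlist
        delayed = concatenate([silence(3.0, RATE), wave])
        rng = np.random.default_rng(4)
        onsets = np.sort(rng.uniform(0.2, delayed.duration - 0.3, 10))
        calls = [(float(t), 0.1, -15.0) for t in onsets]
        rec = synth_recording(delayed, -30.0, calls, noise_level=-70.0, seed=4)
        lag, _ = align_playback(rec, wave)
        assert abs(lag - 3.0) <= 0.01

    def test_stimulus_longer_than_recording_rejected(self, playlist):
        wave, _ = playlist
        short = synth_recording(
            concatenate([silence(1.0, RATE)]), -40.0, [], seed=1
        )
        with pytest.raises(ValueError, match="longer than the recording"):
            align_playback(short, wave)


class TestDetectCalls:
    def test_no_injected_calls_no_events(self, playlist):
        wave, _ = playlist
        rec = synth_recording(wave, -30.0, [], noise_level=-70.0, seed=2)
        lag, _ = align_playback(rec, wave)
        assert detect_calls(rec, wave, lag, CFG) == []

    def test_injected_calls_recovered_with_onsets(self, playlist):
        wave, schedule = playlist
        bout0 = schedule.entries.iloc[0]
        bout1 = schedule.entries.iloc[1]
        onsets = [
            0.40,  # pre
            float(bout0.onset_s) + 0.30,  # mid-song
            float(bout0.onset_s + bout0.duration_s) + 0.80,  # inter-song silence
            float(bout1.onset_s) + 0.50,  # mid-song
            float(schedule.playback_end) + 0.40,  # post
        ]
        calls = [(t, 0.08, -12.0) for t in onsets]
        rec = synth_recording(wave, -32.0, calls, noise_level=-70.0, seed=3)
        lag, _ = align_playback(rec, wave)
        events = detect_calls(rec, wave, lag, CFG)
        assert len(events) == len(onsets)
        for ev, t in zip(events, onsets):
            assert abs(ev.onset - t) <= 0.010
            assert ev.peak_margin >= CFG.margin


class TestAssignWindows:
    def _schedule(self, playlist):
        return playlist[1]

    def test_half_open_bout_boundary(self, playlist):
        schedule = self._schedule(playlist)
        b = schedule.entries.iloc[0]
        end = float(b.onset_s + b.duration_s)
        events = [
            CallEvent(float(b.onset_s), float(b.onset_s) + 0.05, 20.0),
            CallEvent(end, end + 0.05, 20.0),
        ]
        labeled = assign_windows(events, schedule, CFG)
        assert labeled[0].window == "within_song"
        assert labeled[1].window == "inter_song"

    def test_pre_and_post_labels(self, playlist):
        schedule = self._schedule(playlist)
        labeled = assign_windows(
            [
                CallEvent(0.1, 0.15, 20.0),
                CallEvent(schedule.playback_end + 0.2, schedule.playback_end + 0.3, 20.0),
            ],
            schedule,
            CFG,
        )
        assert [e.window for e in labeled] == ["pre", "post"]


class TestTabulateCounts:
    def test_window_counts_conserve_events(self, playlist):
        _, schedule = playlist
        events = assign_windows(
            [
                CallEvent(0.2, 0.25, 15.0),
                CallEvent(schedule.playback_start + 0.1, schedule.playback_start + 0.2, 15.0),
                CallEvent(schedule.playback_end + 0.1, schedule.playback_end + 0.2, 15.0),
            ],
            schedule,
            CFG,
        )
        table = tabulate_counts(events, schedule, CFG)
        assert table["count"].sum() == len(events)

    def test_rate_is_count_over_exposure(self):
        frame = pd.DataFrame(
            {
                "subject": ["b"],
                "session": [1],
                "condition": ["FIXED"],
                "window": ["within_song"],
                "exposure_s": [240.0],
                "count": [12],
            }
        )
        frame["rate"] = frame["count"] / frame["exposure_s"]
        assert frame["rate"].iloc[0] == pytest.approx(0.05)

    def test_zero_events_emit_all_scheduled_cells(self, playlist):
        _, schedule = playlist
        table = tabulate_counts([], schedule, CFG)
        assert set(table["window"]) == {"pre", "within_song", "inter_song", "post"}
        assert (table["count"] == 0).all()

    def test_exposures_cover_pre_playback_post(self, playlist):
        _, schedule = playlist
        cells = scheduled_cells(schedule, CFG)
        playback_span = schedule.playback_end - schedule.playback_start
        expected = CFG.pre_window + playback_span + CFG.post_window
        assert cells["exposure_s"].sum() == pytest.approx(expected, abs=1e-6)

    def test_unlabeled_events_rejected(self, playlist):
        _, schedule = playlist
        with pytest.raises(ValueError, match="window-labeled"):
            tabulate_counts([CallEvent(0.1, 0.2, 12.0)], schedule, CFG)


class TestDependentVariables:
    def test_three_readouts(self):
        table = pd.DataFrame(
            {
                "subject": ["b1"] * 4,
                "session": [1] * 4,
                "condition": ["NONE", "FIXED", "FIXED", "NONE"],
                "window": ["pre", "within_song", "inter_song", "post"],
                "exposure_s": [60.0, 20.0, 200.0, 60.0],
                "count": [1, 8, 4, 2],
            }
        )
        out = dependent_variables(table)
        row = out.iloc[0]
        assert row["total_playback_count"] == 12
        assert row["within_song_count"] == 8
        assert row["playback_rate"] == pytest.approx(12 / 220.0)
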