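"""Motif conditions, bouts, playlists and counterbalancing."""

import numpy as np
import pytest

from finchcall import (
    BoutSpec,
    Waveform,
    build_bout,
    build_motif,
    build_playlist,
    counterbalance_orders,
    manipulated_fraction,
    reverse_token,
)
from finchcall.stimuli import _draw_nonidentity_permutation

RATE = 22_050


class TestReverseToken:
    def test_reversal_is_sample_reversal(self, template):
        token = template.tokens[0]
        rev = reverse_token(token)
        np.testing.assert_array_equal(rev.wave.samples, token.wave.samples[::-1])
        assert rev.reversed_ and not token.reversed_
        assert rev.duration == token.duration

    def test_double_reversal_is_identity(self, template):
        token = template.tokens[1]
        back = reverse_token(reverse_token(token))
        np.testing.assert_array_equal(back.wave.samples, token.wave.samples)
        assert not back.reversed_


class TestBuildMotif:
    def test_fixed_is_independent_of_motif_index(self, template, rng):
        w0, _ = build_motif(template, "FIXED", 0, rng)
        w5, _ = build_motif(template, "FIXED", 5, rng)
        np.testing.assert_array_equal(w0.samples, w5.samples)

    def test_reversal_keeps_syllable_onsets(self, template, rng):
        _, fixed = build_motif(template, "FIXED", 0, rng)
        _, rev = build_motif(template, "REVERSAL", 0, rng)
        np.testing.assert_allclose(
            rev["onset_s"].to_numpy(), fixed["onset_s"].to_numpy()
        )
        assert rev["reversed"].all()

    def test_shuffle_preserves_token_multiset(self, template, rng):
        wave, ann = build_motif(template, "SHUFFLED", 0, rng)
        assert sorted(ann["label"]) == ["a", "b", "c", "d"]
        assert list(ann["label"]) != ["a", "b", "c", "d"]  # natural order excluded

    def test_duration_equal_across_nonrendition_conditions(self, template, rng):
        durations = {
            cond: len(build_motif(template, cond, 0, rng)[0])
            for cond in ("FIXED", "SHUFFLED", "REVERSAL")
        }
        assert len(set(durations.values())) == 1

    def test_rendition_requires_bank(self, template, rng):
        from finchcall import MotifTemplate

        bare = MotifTemplate(tokens=template.tokens, gaps=template.gaps)
        with pytest.raises(ValueError, match="rendition_bank"):
            build_motif(bare, "RENDITION", 0, rng)

    def test_rendition_cycles_through_bank(self, template, rng):
        k = len(template.rendition_bank)
        _, a0 = build_motif(template, "RENDITION", 0, rng)
        _, ak = build_motif(template, "RENDITION", k, rng)
        assert (a0["source_rendition"] == 0).all()
        assert (ak["source_rendition"] == 0).all()  # index k wraps to rendition 0

    def test_shuffle_permutations_are_uniform_over_nonidentity(self):
        # 3 syllables: the 5 non-identity permutations each ~ 1/5
        rng = np.random.default_rng(7)
        counts = {}
        for _ in range(10_000):
            perm = tuple(_draw_nonidentity_permutation(3, rng))
            counts[perm] = counts.get(perm, 0) + 1
        assert (0, 1, 2) not in counts
        assert len(counts) == 5
        for c in counts.values():
            assert abs(c / 10_000 - 0.2) < 0.02


class TestBuildBout:
    def test_fixed_bout_repeats_identical_motifs(self, template):
        spec = BoutSpec("FIXED", n_motifs=8, inter_motif_gap=0.04, seed=1)
        wave, ann = build_bout(template, spec)
        motif_len = len(build_motif(template, "FIXED", 0, np.random.default_rng(0))[0])
        gap_len = int(round(0.04 * RATE))
        first = wave.samples[:motif_len]
        for m in range(1, 8):
            start = m * (motif_len + gap_len)
            np.testing.assert_array_equal(wave.samples[start : start + motif_len], first)

    def test_bout_duration_bookkeeping(self, template):
        spec = BoutSpec("FIXED", n_motifs=4, inter_motif_gap=0.05, seed=0)
        wave, _ = build_bout(template, spec)
        motif_len = len(build_motif(template, "FIXED", 0, np.random.default_rng(0))[0])
        expected = 4 * motif_len + 3 * int(round(0.05 * RATE))
        assert len(wave) == expected

    @pytest.mark.parametrize(
        "condition,expected",
        [
            ("FIXED", 0.0),
            ("REVERSAL", 1.0),
            ("FIRST_MOTIF_REVERSAL", 0.125),
            ("LAST_MOTIF_REVERSAL", 0.125),
        ],
    )
    def test_manipulated_fraction_of_8_motif_bouts(self, template, condition, expected):
        _, ann = build_bout(template, BoutSpec(condition, n_motifs=8, seed=2))
        assert manipulated_fraction(ann) == expected

    def test_partial_reversal_marks_only_the_edge_motif(self, template):
        _, ann = build_bout(
            template, BoutSpec("LAST_MOTIF_REVERSAL", n_motifs=8, seed=3)
        )
        by_motif = ann.groupby("motif_index")["reversed"].all()
        assert by_motif[7] and not by_motif[:7].any()
        assert len(ann) == 8 * template.n_syllables

    def test_partial_reversal_needs_two_motifs(self):
        with pytest.raises(ValueError, match=">= 2 motifs"):
            BoutSpec("FIRST_MOTIF_REVERSAL", n_motifs=1)

    def test_identical_seed_reproduces_bout(self, template):
        spec = BoutSpec("SHUFFLED", n_motifs=3, seed=42)
        w1, a1 = build_bout(template, spec)
        w2, a2 = build_bout(template, spec)
        np.testing.assert_array_equal(w1.samples, w2.samples)
        assert a1.equals(a2)


class TestBuildPlaylist:
    def _bout(self, duration=2.2):
        return Waveform(0.1 * np.ones(int(duration * RATE)), RATE)

    def test_total_duration_arithmetic(self):
        bouts = [(self._bout(2.2), {}) for _ in range(6)]
        wave, schedule = build_playlist(bouts, inter_song_silence=40.0)
        assert wave.duration == pytest.approx(6 * 2.2 + 5 * 40.0, abs=1e-3)
        assert len(schedule.entries) == 6

    def test_silence_between_songs_only(self):
        bouts = [(self._bout(1.0), {}) for _ in range(3)]
        wave, schedule = build_playlist(
            bouts, inter_song_silence=2.0, lead_in=0.5, lead_out=0.25
        )
        assert schedule.entries["onset_s"].iloc[0] == pytest.approx(0.5)
        assert wave.duration == pytest.approx(0.5 + 3 * 1.0 + 2 * 2.0 + 0.25, abs=1e-3)

    def test_consecutive_onsets_obey_gap_invariant(self):
        bouts = [(self._bout(1.5), {}) for _ in range(4)]
        _, schedule = build_playlist(bouts, inter_song_silence=3.0)
        onsets = schedule.entries["onset_s"].to_numpy()
        durations = schedule.entries["duration_s"].to_numpy()
        np.testing.assert_allclose(np.diff(onsets), durations[:-1] + 3.0, atol=1e-6)

    def test_two_bouts_per_male_layout(self):
        bouts = []
        for repeat in range(2):
            for male in ["m1", "m2", "m3", "m4", "m5"]:
                bouts.append((self._bout(1.0), {"male_id": male}))
        _, schedule = build_playlist(bouts, inter_song_silence=1.0)
        per_male = schedule.entries.groupby("male_id").size()
        assert (per_male == 2).all() and len(per_male) == 5

    def test_schedule_json_round_trip(self, tmp_path):
        bouts = [(self._bout(1.0), {"condition": "FIXED"}) for _ in range(2)]
        _, schedule = build_playlist(bouts, inter_song_silence=5.0, session=2)
        path = tmp_path / "sched.json"
        schedule.to_json(path)
        from finchcall import PlaybackSchedule

        loaded = PlaybackSchedule.from_json(path)
        assert loaded.session == 2
        assert loaded.entries["onset_s"].tolist() == schedule.entries["onset_s"].tolist()


class TestCounterbalance:
    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_cyclic_latin_square(self, n):
        conditions = [f"C{i}" for i in range(n)]
        orders = counterbalance_orders(conditions)
        assert len(orders) == n
        for pos in range(n):
            seen = {order[pos] for order in orders}
            assert seen == set(conditions)  # each condition once per position

    def test_unbalanced_version_count_warns(self):
        with pytest.warns(UserWarning, match="not a balanced"):
            orders = counterbalance_orders(["A", "B", "C"], n_versions=2)
        assert len(orders) == 2
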