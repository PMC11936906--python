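"""Score female calls in a synthetic cage recording.

Builds a short FIXED-condition playlist, mixes in five female calls 20 dB
above the playback level plus background noise, then runs the scorer:
align the known stimulus, detect level excesses, assign scoring windows,
and tabulate counts per (condition, window) cell.
"""

import dataclasses

from finchcall import (
    RenditionJitter,
    ScoringConfig,
    align_playback,
    assign_windows,
    detect_calls,
    example_motif_spec,
    synth_recording,
    tabulate_counts,
    template_from_motif_spec,
)
from finchcall.designs import SESSION_PER_CONDITION, single_condition_playlist

template = template_from_motif_spec(
    example_motif_spec(4), RenditionJitter(seed=3), rate=22_050
)
preset = dataclasses.replace(SESSION_PER_CONDITION, n_songs_per_playback=3, inter_song_silence_s=5.0)
playlist, schedule = single_condition_playlist(
    template, preset, "FIXED", lead_in=5.0, lead_out=5.0
)
print(f"playlist: {playlist.duration:.1f} s, {len(schedule.entries)} song bouts")

bout0 = schedule.entries.iloc[0]
calls = [
    (2.0, 0.1, -12.0),                                   # pre-playback
    (float(bout0.onset_s) + 0.4, 0.1, -12.0),            # within the first song
    (float(bout0.onset_s + bout0.duration_s) + 2.0, 0.1, -12.0),  # inter-song
    (float(schedule.playback_end) + 1.0, 0.1, -12.0),    # post-playback
    (float(schedule.playback_end) + 2.5, 0.1, -12.0),
]
recording = synth_recording(playlist, -32.0, calls, noise_level=-70.0, seed=5)

cfg = ScoringConfig(pre_window=5.0, post_window=5.0)
lag, score = align_playback(recording, playlist)
print(f"alignment: lag {lag*1000:.1f} ms, envelope correlation {score:.3f}")

events = detect_calls(recording, playlist, lag, cfg)
events = assign_windows(events, schedule.shifted(lag), cfg)
print(f"detected {len(events)} calls (injected {len(calls)}):")
for ev in events:
    print(f"  onset {ev.onset:7.3f} s  margin {ev.peak_margin:5.1f} dB  {ev.window}")

table = tabulate_counts(events, schedule.shifted(lag), cfg)
print("\ncount table (one row per scheduled cell):")
print(table.to_string(index=False))
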