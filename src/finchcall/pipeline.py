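"""End-to-end composition: simulate calls, render a cage recording, score it.

Glue for full-pipeline checks and demos: build a stimulus playlist from a
synthetic motif, draw call times from the behavioral model, mix them into a
recording in which calls are louder than the playback, then run the scorer
and compare its count table against the simulated ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .response import ResponseParams, enforce_event_separation, simulate_calls
from .scoring import (
    ScoringConfig,
    align_playback,
    assign_windows,
    detect_calls,
    tabulate_counts,
)
from .song_synth import RenditionJitter, example_motif_spec, synth_recording
from .stimuli import CONDITIONS, BoutSpec, build_bout, build_playlist, template_from_motif_spec

__all__ = ["ClosureResult", "run_closure_scenario"]


@dataclass
class ClosureResult:
    """Ground truth vs scored outcome of one simulate-render-score run."""

    condition: str
    true_counts: dict[str, int]  # per window
    scored_counts: dict[str, int]
    n_injected: int
    lag: float

    @property
    def exact(self) -> bool:
        return self.true_counts == self.scored_counts


def run_closure_scenario(
    seed: int,
    *,
    rate: int = 22_050,
    n_songs: int = 3,
    n_motifs: int = 2,
    inter_song_silence: float = 1.5,
    pre_post: float = 1.0,
    playback_level: float = -35.0,
    call_level: float = -10.0,
    call_duration: float = 0.080,
    base_rate: float = 0.6,
    cfg: ScoringConfig | None = None,
) -> ClosureResult:
    """One randomized simulate -> render -> score -> tabulate round trip.

    The scenario draws a random motif condition, simulates Poisson call
    times over pre/playback/post, keeps only calls that are resolvable as
    separate events (separated by well over the scorer's merge gap) and
    unambiguous in window (clear of every bout and playback boundary), mixes
    them 25 dB above the playback component, and checks that the scored
    per-window counts equal the simulated ones.
    """
    if cfg is None:
        cfg = ScoringConfig(pre_window=pre_post, post_window=pre_post)
    rng = np.random.default_rng(seed)
    condition = str(rng.choice(CONDITIONS))
    template = template_from_motif_spec(
        example_motif_spec(3),
        RenditionJitter(seed=seed),
        n_renditions=2,
        rate=rate,
    )
    bouts = []
    for i in range(n_songs):
        wave, _ = build_bout(
            template,
            BoutSpec(condition, n_motifs=n_motifs, inter_motif_gap=0.05, seed=seed + i),
        )
        bouts.append((wave, {"condition": condition, "bout_id": f"b{i}"}))
    playlist, schedule = build_playlist(
        bouts, inter_song_silence, lead_in=pre_post, lead_out=pre_post
    )

    params = ResponseParams(base_rate=base_rate, silence_ratio=0.5, seed=seed)
    onsets = simulate_calls(
        schedule, params, rng=rng, pre_s=pre_post, post_s=pre_post
    )
    onsets = enforce_event_separation(
        onsets, call_duration + 4 * cfg.min_inter_call_gap + 0.1
    )
    # keep calls clear of every window boundary and of the recording edges
    boundaries = [schedule.playback_start, schedule.playback_end]
    for b0, b1, _ in schedule.bout_intervals():
        boundaries.extend([b0, b1])
    clear = 0.060
    kept = [
        t
        for t in onsets
        if 0.05 <= t
        and t + call_duration <= playlist.duration - 0.05
        and all(not (b - clear < t < b + clear or b - clear < t + call_duration < b + clear)
                for b in boundaries)
    ]
    calls = [(t, call_duration, call_level) for t in kept]
    recording = synth_recording(
        playlist, playback_level, calls, noise_level=-75.0, seed=seed
    )
    lag, _ = align_playback(recording, playlist)
    events = detect_calls(recording, playlist, lag, cfg)
    events = assign_windows(events, schedule.shifted(lag), cfg)
    scored = tabulate_counts(events, schedule.shifted(lag), cfg)

    from .response import _window_of  # ground-truth windowing rule

    true_counts = {w: 0 for w in ("pre", "within_song", "inter_song", "post")}
    for t in kept:
        true_counts[_window_of(t, schedule)] += 1
    scored_counts = dict(
        scored.groupby("window")["count"].sum().reindex(true_counts, fill_value=0)
    )
    scored_counts = {k: int(v) for k, v in scored_counts.items()}
    return ClosureResult(
        condition=condition,
        true_counts=true_counts,
        scored_counts=scored_counts,
        n_injected=len(kept),
        lag=lag,
    )
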