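"""Playback-design presets.

Four layouts cover the usual ways of arranging motif conditions:

* ``SESSION_PER_CONDITION`` — short 4-motif bouts, one condition per
  session, conditions counterbalanced across sessions;
* ``SINGLE_PLAYBACK_4COND`` / ``SINGLE_PLAYBACK_2COND`` — long 8-motif
  bouts with all conditions inside one playlist, order counterbalanced
  across playlist versions;
* ``MULTI_MALE`` — one condition per playback, songs pooled from five
  males with two songs each, partial-reversal conditions included.

Each preset records only the unambiguous design fields (conditions,
sessions, motifs per song, songs per playback, males, inter-song silence);
helpers turn a preset plus motif templates into playlists.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Waveform
from .stimuli import (
    BoutSpec,
    MotifTemplate,
    PlaybackSchedule,
    build_bout,
    build_playlist,
    counterbalance_orders,
)

__all__ = [
    "DesignPreset",
    "SESSION_PER_CONDITION",
    "SINGLE_PLAYBACK_4COND",
    "SINGLE_PLAYBACK_2COND",
    "MULTI_MALE",
    "PRESETS",
    "single_condition_playlist",
    "mixed_condition_playlist",
    "multi_male_playlist",
]


@dataclass(frozen=True)
class DesignPreset:
    """Design fields of one playback-experiment layout."""

    name: str
    conditions: tuple[str, ...]
    n_sessions: int
    n_motifs_per_song: int
    n_songs_per_playback: int
    inter_song_silence_s: float
    n_males: int = 1
    songs_per_male: int | None = None  # None: all songs from one male
    single_playback: bool = False  # all conditions inside one playlist

    @property
    def n_versions(self) -> int:
        """Counterbalancing versions: one per condition (cyclic design)."""
        return len(self.conditions)


SESSION_PER_CONDITION = DesignPreset(
    name="session_per_condition",
    conditions=("FIXED", "REVERSAL", "SHUFFLED", "RENDITION"),
    n_sessions=4,
    n_motifs_per_song=4,
    n_songs_per_playback=6,
    inter_song_silence_s=40.0,
)

SINGLE_PLAYBACK_4COND = DesignPreset(
    name="single_playback_four_conditions",
    conditions=("FIXED", "REVERSAL", "SHUFFLED", "RENDITION"),
    n_sessions=1,
    n_motifs_per_song=8,
    n_songs_per_playback=8,
    inter_song_silence_s=45.0,
    single_playback=True,
)

SINGLE_PLAYBACK_2COND = DesignPreset(
    name="single_playback_two_conditions",
    conditions=("FIXED", "REVERSAL"),
    n_sessions=2,
    n_motifs_per_song=8,
    n_songs_per_playback=8,
    inter_song_silence_s=45.0,
    single_playback=True,
)

MULTI_MALE = DesignPreset(
    name="multi_male_partial_reversal",
    conditions=("FIXED", "REVERSAL", "FIRST_MOTIF_REVERSAL", "LAST_MOTIF_REVERSAL"),
    n_sessions=4,
    n_motifs_per_song=8,
    n_songs_per_playback=10,
    inter_song_silence_s=45.0,
    n_males=5,
    songs_per_male=2,
)

PRESETS = {p.name: p for p in (SESSION_PER_CONDITION, SINGLE_PLAYBACK_4COND, SINGLE_PLAYBACK_2COND, MULTI_MALE)}


def single_condition_playlist(
    template: MotifTemplate,
    preset: DesignPreset,
    condition: str,
    *,
    inter_motif_gap: float = 0.060,
    lead_in: float = 0.0,
    lead_out: float = 0.0,
    seed: int = 0,
    session: int = 1,
    subject: str = "",
) -> tuple[Waveform, PlaybackSchedule]:
    """One-condition playlist: every song is a bout of ``condition``."""
    bouts = []
    for i in range(preset.n_songs_per_playback):
        spec = BoutSpec(
            condition=condition,
            n_motifs=preset.n_motifs_per_song,
            inter_motif_gap=inter_motif_gap,
            seed=seed + i,
        )
        wave, _ = build_bout(template, spec)
        bouts.append(
            (wave, {"bout_id": f"{condition}_{i}", "condition": condition,
                    "male_id": template.male_id})
        )
    return build_playlist(
        bouts,
        preset.inter_song_silence_s,
        lead_in,
        lead_out,
        session=session,
        subject=subject,
    )


def mixed_condition_playlist(
    template: MotifTemplate,
    preset: DesignPreset,
    version: int,
    *,
    inter_motif_gap: float = 0.060,
    lead_in: float = 0.0,
    lead_out: float = 0.0,
    seed: int = 0,
    session: int = 1,
    subject: str = "",
) -> tuple[Waveform, PlaybackSchedule]:
    """All conditions in one playlist, order set by counterbalancing version.

    Conditions appear in the cyclic-Latin-square order for ``version``, each
    contributing ``n_songs_per_playback / n_conditions`` consecutive songs.
    """
    if not preset.single_playback:
        raise ValueError(f"{preset.name} is not a single-playback design")
    orders = counterbalance_orders(list(preset.conditions))
    order = orders[version % len(orders)]
    per_cond, rem = divmod(preset.n_songs_per_playback, len(order))
    if rem:
        raise ValueError("songs per playback must divide evenly across conditions")
    bouts = []
    i = 0
    for condition in order:
        for _ in range(per_cond):
            spec = BoutSpec(
                condition=condition,
                n_motifs=preset.n_motifs_per_song,
                inter_motif_gap=inter_motif_gap,
                seed=seed + i,
            )
            wave, _ = build_bout(template, spec)
            bouts.append(
                (wave, {"bout_id": f"{condition}_{i}", "condition": condition,
                        "male_id": template.male_id})
            )
            i += 1
    wave, schedule = build_playlist(
        bouts,
        preset.inter_song_silence_s,
        lead_in,
        lead_out,
        session=session,
        subject=subject,
        order_version=version,
    )
    return wave, schedule


def multi_male_playlist(
    templates: list[MotifTemplate],
    preset: DesignPreset,
    condition: str,
    *,
    inter_motif_gap: float = 0.060,
    lead_in: float = 0.0,
    lead_out: float = 0.0,
    seed: int = 0,
    session: int = 1,
    subject: str = "",
) -> tuple[Waveform, PlaybackSchedule]:
    """One condition, songs drawn from several males.

    Each male contributes exactly ``songs_per_male`` bouts; males alternate
    so no male is heard twice in a row.
    """
    if preset.songs_per_male is None:
        raise ValueError(f"{preset.name} is a single-male design")
    if len(templates) != preset.n_males:
        raise ValueError(f"{preset.name} needs {preset.n_males} male templates")
    if preset.n_males * preset.songs_per_male != preset.n_songs_per_playback:
        raise ValueError("male x songs geometry does not match songs per playback")
    bouts = []
    i = 0
    for repeat in range(preset.songs_per_male):
        for template in templates:
            spec = BoutSpec(
                condition=condition,
                n_motifs=preset.n_motifs_per_song,
                inter_motif_gap=inter_motif_gap,
                seed=seed + i,
            )
            wave, _ = build_bout(template, spec)
            bouts.append(
                (wave, {"bout_id": f"{condition}_{template.male_id}_{repeat}",
                        "condition": condition, "male_id": template.male_id})
            )
            i += 1
    return build_playlist(
        bouts,
        preset.inter_song_silence_s,
        lead_in,
        lead_out,
        session=session,
        subject=subject,
    )
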