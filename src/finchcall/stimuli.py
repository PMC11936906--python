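"""Experimental stimulus construction.

Builds the six motif conditions used in song-playback experiments —

* ``FIXED``: one reference motif repeated verbatim,
* ``RENDITION``: consecutive natural renditions of the motif,
* ``REVERSAL``: every syllable spectro-temporally reversed in place,
* ``SHUFFLED``: syllable order freshly permuted within each motif,
* ``FIRST_MOTIF_REVERSAL`` / ``LAST_MOTIF_REVERSAL``: only the first / last
  motif of the bout reversed —

then assembles bouts (motifs joined by a constant inter-motif silence),
playlists (bouts joined by a constant inter-song silence) and cyclic
Latin-square condition orders for counterbalancing across subjects.

All conditions share one timing skeleton: syllable and gap *slots* are
positional, so reversal and shuffling never move onsets, and every condition
of a template yields the identical total duration.  Each bout draws its
randomness from a single seed, hierarchically split per motif, so stimuli
regenerate exactly from their metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Segment, Waveform, concatenate, silence
from .preprocess import SyllableToken

__all__ = [
    "CONDITIONS",
    "MotifTemplate",
    "BoutSpec",
    "PlaybackSchedule",
    "reverse_token",
    "build_motif",
    "build_bout",
    "manipulated_fraction",
    "build_playlist",
    "counterbalance_orders",
    "template_from_motif_spec",
]

CONDITIONS = (
    "FIXED",
    "SHUFFLED",
    "REVERSAL",
    "RENDITION",
    "FIRST_MOTIF_REVERSAL",
    "LAST_MOTIF_REVERSAL",
)

_PARTIAL = {"FIRST_MOTIF_REVERSAL", "LAST_MOTIF_REVERSAL"}

ANNOTATION_COLUMNS = [
    "motif_index",
    "position",
    "source_rendition",
    "reversed",
    "onset_s",
    "duration_s",
    "label",
]


@dataclass(frozen=True)
class MotifTemplate:
    """Reference motif: ordered tokens, gaps, and an optional rendition bank.

    ``gaps`` are the inter-syllable silences of the reference rendition, in
    seconds; every rendition in the bank must have the reference's syllable
    count (zebra finch motifs are stereotyped in structure, variable only in
    fine acoustics).
    """

    tokens: tuple[SyllableToken, ...]
    gaps: tuple[float, ...]
    rendition_bank: tuple[tuple[SyllableToken, ...], ...] | None = None
    male_id: str = ""

    def __post_init__(self) -> None:
        tokens = tuple(self.tokens)
        gaps = tuple(float(g) for g in self.gaps)
        if len(tokens) < 1:
            raise ValueError("template needs at least one token")
        if len(gaps) != len(tokens) - 1:
            raise ValueError("need exactly len(tokens) - 1 gaps")
        if self.rendition_bank is not None:
            bank = tuple(tuple(r) for r in self.rendition_bank)
            if any(len(r) != len(tokens) for r in bank):
                raise ValueError("every bank rendition must match the syllable count")
            object.__setattr__(self, "rendition_bank", bank)
        object.__setattr__(self, "tokens", tokens)
        object.__setattr__(self, "gaps", gaps)

    @property
    def n_syllables(self) -> int:
        return len(self.tokens)

    @property
    def rate(self) -> int:
        return self.tokens[0].wave.rate


@dataclass(frozen=True)
class BoutSpec:
    """Recipe for one song bout."""

    condition: str
    n_motifs: int = 4
    inter_motif_gap: float = 0.060
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; one of {CONDITIONS}"
            )
        if self.n_motifs < 1:
            raise ValueError("a bout needs at least one motif")
        if self.inter_motif_gap < 0:
            raise ValueError("inter-motif gap must be non-negative")
        if self.condition in _PARTIAL and self.n_motifs < 2:
            raise ValueError(
                f"{self.condition} is a partial manipulation and needs >= 2 motifs"
            )


@dataclass
class PlaybackSchedule:
    """Ordered bouts with absolute onsets — the bridge to call scoring.

    ``entries`` has columns ``bout_id, condition, male_id, onset_s,
    duration_s`` sorted by onset; consecutive onsets differ by the previous
    bout's duration plus ``inter_song_silence`` (silence between songs only).
    ``total_duration`` covers lead-in, bouts, inter-song silences and
    lead-out.
    """

    entries: pd.DataFrame
    inter_song_silence: float
    session: int = 1
    subject: str = ""
    order_version: int = 0
    total_duration: float = 0.0

    def __post_init__(self) -> None:
        e = self.entries
        if not e["onset_s"].is_monotonic_increasing:
            raise ValueError("schedule entries must be sorted by onset")
        ends = e["onset_s"] + e["duration_s"]
        if (e["onset_s"].to_numpy()[1:] < ends.to_numpy()[:-1] - 1e-9).any():
            raise ValueError("schedule entries overlap")

    @property
    def playback_start(self) -> float:
        return float(self.entries["onset_s"].iloc[0])

    @property
    def playback_end(self) -> float:
        last = self.entries.iloc[-1]
        return float(last["onset_s"] + last["duration_s"])

    def bout_intervals(self) -> list[tuple[float, float, str]]:
        return [
            (float(r.onset_s), float(r.onset_s + r.duration_s), str(r.condition))
            for r in self.entries.itertuples()
        ]

    def shifted(self, lag: float) -> "PlaybackSchedule":
        """Schedule in recording time: all onsets moved by ``lag`` seconds."""
        entries = self.entries.copy()
        entries["onset_s"] = entries["onset_s"] + lag
        return PlaybackSchedule(
            entries,
            self.inter_song_silence,
            self.session,
            self.subject,
            self.order_version,
            self.total_duration + lag,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subject": self.subject,
            "session": self.session,
            "order_version": self.order_version,
            "inter_song_silence": self.inter_song_silence,
            "total_duration": self.total_duration,
            "entries": self.entries.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlaybackSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(
            entries=pd.DataFrame(payload["entries"]),
            inter_song_silence=payload["inter_song_silence"],
            session=payload["session"],
            subject=payload["subject"],
            order_version=payload["order_version"],
            total_duration=payload["total_duration"],
        )


def reverse_token(token: SyllableToken) -> SyllableToken:
    """Spectro-temporal reversal: play the syllable's samples backward.

    Duration, RMS and position metadata are unchanged; the ``reversed_``
    flag is toggled, so reversal is an involution.
    """
    return token.with_wave(
        Waveform(token.wave.samples[::-1].copy(), token.wave.rate),
        reversed_=not token.reversed_,
    )


def _tokens_for(template: MotifTemplate, condition: str, motif_index: int):
    """Source tokens and their bank rendition index for one motif slot."""
    if condition == "RENDITION":
        if not template.rendition_bank:
            raise ValueError("RENDITION requires a template with a rendition_bank")
        k = motif_index % len(template.rendition_bank)
        return template.rendition_bank[k], k
    return template.tokens, -1


def _draw_nonidentity_permutation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform draw over the n! - 1 permutations that differ from identity."""
    identity = np.arange(n)
    while True:
        perm = rng.permutation(n)
        if n == 1 or not np.array_equal(perm, identity):
            return perm


def build_motif(
    template: MotifTemplate,
    condition: str,
    motif_index: int,
    rng: np.random.Generator,
) -> tuple[Waveform, pd.DataFrame]:
    """Render one motif under a condition.

    Gap slots are positional: under ``SHUFFLED``, gap *j* stays between
    positions *j* and *j+1* whatever tokens land there, so the normalized
    timing grid is shared by all conditions.  ``SHUFFLED`` draws a fresh
    permutation per motif and redraws if it equals the natural order.
    Partial-reversal conditions are bout-level and render as ``FIXED`` here.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    base = "FIXED" if condition in _PARTIAL else condition
    tokens, source_rendition = _tokens_for(template, base, motif_index)
    order = np.arange(template.n_syllables)
    if base == "SHUFFLED":
        order = _draw_nonidentity_permutation(template.n_syllables, rng)
    placed = [tokens[j] for j in order]
    if base == "REVERSAL":
        placed = [reverse_token(t) for t in placed]
    pieces: list[Waveform] = []
    rows = []
    onset = 0.0
    for slot, token in enumerate(placed):
        rows.append(
            {
                "motif_index": motif_index,
                "position": slot,
                "source_rendition": source_rendition,
                "reversed": token.reversed_,
                "onset_s": onset,
                "duration_s": token.duration,
                "label": chr(ord("a") + int(order[slot]) % 26),
            }
        )
        pieces.append(token.wave)
        onset += token.duration
        if slot < len(template.gaps):
            pieces.append(silence(template.gaps[slot], template.rate))
            onset += template.gaps[slot]
    return concatenate(pieces), pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def build_bout(
    template: MotifTemplate, spec: BoutSpec
) -> tuple[Waveform, pd.DataFrame]:
    """Render a song bout: motifs joined by a constant inter-motif silence.

    ``FIRST_MOTIF_REVERSAL`` / ``LAST_MOTIF_REVERSAL`` reverse every token
    of motif 0 / motif ``n_motifs - 1`` only; the annotation marks exactly
    the reversed syllables.  The annotation has one row per syllable slot
    (``n_motifs x syllables_per_motif``) with bout-relative onsets.
    """
    seeds = np.random.SeedSequence(spec.seed & 0x7FFFFFFF).spawn(spec.n_motifs)
    pieces: list[Waveform] = []
    frames: list[pd.DataFrame] = []
    onset = 0.0
    for m in range(spec.n_motifs):
        rng = np.random.default_rng(seeds[m])
        condition = spec.condition
        if spec.condition == "FIRST_MOTIF_REVERSAL":
            condition = "REVERSAL" if m == 0 else "FIXED"
        elif spec.condition == "LAST_MOTIF_REVERSAL":
            condition = "REVERSAL" if m == spec.n_motifs - 1 else "FIXED"
        wave, ann = build_motif(template, condition, m, rng)
        ann = ann.copy()
        ann["onset_s"] += onset
        frames.append(ann)
        pieces.append(wave)
        onset += wave.duration
        if m < spec.n_motifs - 1:
            pieces.append(silence(spec.inter_motif_gap, template.rate))
            onset += spec.inter_motif_gap
    return concatenate(pieces), pd.concat(frames, ignore_index=True)


def manipulated_fraction(annotation: pd.DataFrame) -> float:
    """Fraction of syllable slots carrying a reversed token."""
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    return float(annotation["reversed"].mean())


def build_playlist(
    bouts: list[tuple[Waveform, dict]],
    inter_song_silence: float,
    lead_in: float = 0.0,
    lead_out: float = 0.0,
    *,
    session: int = 1,
    subject: str = "",
    order_version: int = 0,
) -> tuple[Waveform, PlaybackSchedule]:
    """Join bouts into one playback waveform with its schedule.

    Layout: lead-in silence, then bouts separated by ``inter_song_silence``
    (between songs only — no silence after the last song), then lead-out
    silence.  Each metadata dict may carry ``bout_id``, ``condition`` and
    ``male_id``; the schedule records absolute onsets.
    """
    if not bouts:
        raise ValueError("a playlist needs at least one bout")
    rate = bouts[0][0].rate
    pieces: list[Waveform] = []
    if lead_in > 0:
        pieces.append(silence(lead_in, rate))
    rows = []
    onset = lead_in
    for i, (wave, meta) in enumerate(bouts):
        rows.append(
            {
                "bout_id": meta.get("bout_id", f"bout{i}"),
                "condition": meta.get("condition", ""),
                "male_id": meta.get("male_id", ""),
                "onset_s": onset,
                "duration_s": wave.duration,
            }
        )
        pieces.append(wave)
        onset += wave.duration
        if i < len(bouts) - 1:
            pieces.append(silence(inter_song_silence, rate))
            onset += inter_song_silence
    if lead_out > 0:
        pieces.append(silence(lead_out, rate))
    waveform = concatenate(pieces)
    schedule = PlaybackSchedule(
        entries=pd.DataFrame(
            rows, columns=["bout_id", "condition", "male_id", "onset_s", "duration_s"]
        ),
        inter_song_silence=inter_song_silence,
        session=session,
        subject=subject,
        order_version=order_version,
        total_duration=waveform.duration,
    )
    return waveform, schedule


def counterbalance_orders(
    conditions: list[str], n_versions: int | None = None
) -> list[list[str]]:
    """Cyclic Latin-square condition orders.

    With ``n_versions`` equal to the number of conditions (the default),
    each condition appears exactly once at each serial position across the
    orderings — the counterbalancing used when presentation order must not
    confound condition.  Other ``n_versions`` still return cyclic rotations
    but the design is no longer balanced and a warning is issued.
    """
    if not conditions:
        raise ValueError("no conditions to order")
    k = len(conditions)
    if n_versions is None:
        n_versions = k
    if n_versions != k:
        warnings.warn(
            f"{n_versions} versions of {k} conditions is not a balanced "
            "Latin square; returning cyclic rotations",
            stacklevel=2,
        )
    return [
        [conditions[(pos + v) % k] for pos in range(k)] for v in range(n_versions)
    ]


def template_from_motif_spec(
    motif_spec,
    jitter=None,
    n_renditions: int = 4,
    rate: int | None = None,
    male_id: str = "",
    ramp: float = 0.005,
):
    """Synthesize a :class:`MotifTemplate` (with rendition bank) end to end.

    Convenience composition of the synthesis and extraction stages: render
    ``n_renditions`` jittered renditions of ``motif_spec``, extract ramped
    tokens using the generator's own segment labels, and use rendition 0 as
    the reference.  The reference gaps are taken from rendition 0.
    """
    from .core import DEFAULT_RATE
    from .preprocess import extract_syllable
    from .song_synth import RenditionJitter, synth_motif_rendition

    if jitter is None:
        jitter = RenditionJitter()
    if rate is None:
        rate = DEFAULT_RATE
    bank: list[tuple[SyllableToken, ...]] = []
    ref_gaps: tuple[float, ...] = ()
    for r in range(n_renditions):
        wave, segs = synth_motif_rendition(motif_spec, jitter, r, rate)
        tokens = tuple(
            extract_syllable(
                wave, seg, ramp, male_id=male_id, rendition_index=r, position=i
            )
            for i, seg in enumerate(segs)
        )
        bank.append(tokens)
        if r == 0:
            ref_gaps = tuple(
                (segs[i + 1].start - segs[i].end) / rate for i in range(len(segs) - 1)
            )
    return MotifTemplate(
        tokens=bank[0], gaps=ref_gaps, rendition_bank=tuple(bank), male_id=male_id
    )
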