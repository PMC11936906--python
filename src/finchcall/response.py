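"""Simulation of female call behavior under the analysis model.

Calls are generated by a piecewise-constant-rate (inhomogeneous) Poisson
process: during a song bout of condition *c*, in session *s*, for bird *b*,

    rate = base_rate * multiplier[c] * habituation**(s - 1) * exp(offset_b)

and outside bouts the rate is further multiplied by ``silence_ratio``.
Bird offsets are log-normal random intercepts (``offset_b ~ N(0,
bird_sd^2)``) — the heterogeneity structure a random-factor count analysis
assumes.  Habituation is a single geometric per-session decay, matching the
monotone decline of calling across repeated sessions without asserting any
finer functional form.  Within-bout rate is constant; no finer temporal
structure is modelled.

``simulate_experiment`` composes a playback-design geometry with the process
to produce the count table the statistics run on; optionally it returns the
raw event times, and events can be rendered into recording audio (via
``song_synth.synth_recording``) for full-pipeline simulate → render →
score → tabulate tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import NO_CONDITION, WINDOWS
from .stimuli import PlaybackSchedule, counterbalance_orders

__all__ = [
    "ResponseParams",
    "ScheduleGeometry",
    "ExperimentDesign",
    "simulate_calls",
    "simulate_experiment",
    "abstract_schedule",
    "enforce_event_separation",
]


@dataclass(frozen=True)
class ResponseParams:
    """Parameters of the call-behavior model.

    base_rate
        Calls per second during song bouts for the reference condition,
        reference bird, first session.
    silence_ratio
        Rate multiplier outside song bouts (inter-song, pre, post).
    condition_multipliers
        Map condition -> rate multiplier (e.g. a strong REVERSAL suppression
        is a multiplier far below 1).  Missing conditions default to 1.
    habituation
        Per-session geometric decay ``h``: session *s* rates carry a factor
        ``h**(s - 1)``.  ``h < 1`` is habituation, ``h > 1`` sensitization.
    bird_sd
        SD of per-bird log-rate offsets.
    """

    base_rate: float = 0.5
    silence_ratio: float = 0.1
    condition_multipliers: dict = field(default_factory=dict)
    habituation: float = 1.0
    bird_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.silence_ratio < 0:
            raise ValueError("silence_ratio must be >= 0")
        if any(m < 0 for m in self.condition_multipliers.values()):
            raise ValueError("condition multipliers must be >= 0")
        if self.habituation <= 0:
            raise ValueError("habituation multiplier must be > 0")
        if self.bird_sd < 0:
            raise ValueError("bird_sd must be >= 0")

    def multiplier(self, condition: str) -> float:
        return float(self.condition_multipliers.get(condition, 1.0))


@dataclass(frozen=True)
class ScheduleGeometry:
    """Playback geometry of one session, abstracted from audio."""

    n_songs: int = 6
    song_duration_s: float = 2.9
    inter_song_silence_s: float = 40.0
    pre_s: float = 60.0
    post_s: float = 60.0

    def __post_init__(self) -> None:
        if self.n_songs < 1:
            raise ValueError("need at least one song")
        if min(self.song_duration_s, self.pre_s, self.post_s) <= 0:
            raise ValueError("durations must be positive")
        if self.inter_song_silence_s < 0:
            raise ValueError("inter-song silence must be >= 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Who hears what when: birds x sessions x counterbalanced conditions.

    ``condition_orders`` holds one condition sequence per counterbalancing
    version (bird *b* follows ``condition_orders[b % n_versions]``); session
    *s* presents the order's entry ``s - 1``.
    """

    n_birds: int
    n_sessions: int
    condition_orders: tuple[tuple[str, ...], ...]
    geometry: ScheduleGeometry = ScheduleGeometry()

    def __post_init__(self) -> None:
        if self.n_birds < 1:
            raise ValueError("need at least one bird")
        orders = tuple(tuple(o) for o in self.condition_orders)
        if not orders:
            raise ValueError("need at least one condition order")
        if any(len(o) < self.n_sessions for o in orders):
            raise ValueError("each order must cover every session")
        object.__setattr__(self, "condition_orders", orders)

    @classmethod
    def counterbalanced(
        cls,
        n_birds: int,
        conditions: list[str],
        geometry: ScheduleGeometry = ScheduleGeometry(),
        n_sessions: int | None = None,
    ) -> "ExperimentDesign":
        orders = counterbalance_orders(list(conditions))
        return cls(
            n_birds=n_birds,
            n_sessions=n_sessions if n_sessions is not None else len(conditions),
            condition_orders=tuple(tuple(o) for o in orders),
            geometry=geometry,
        )

    def condition_for(self, bird: int, session: int) -> str:
        return self.condition_orders[bird % len(self.condition_orders)][session - 1]


def abstract_schedule(
    geometry: ScheduleGeometry,
    condition: str,
    *,
    subject: str = "",
    session: int = 1,
) -> PlaybackSchedule:
    """Schedule of a single-condition playback with the given geometry.

    Onsets start after a lead-in of ``pre_s`` seconds so that the schedule's
    time axis matches a recording that includes the scored pre window.
    """
    onsets = geometry.pre_s + np.arange(geometry.n_songs) * (
        geometry.song_duration_s + geometry.inter_song_silence_s
    )
    entries = pd.DataFrame(
        {
            "bout_id": [f"bout{i}" for i in range(geometry.n_songs)],
            "condition": condition,
            "male_id": "",
            "onset_s": onsets,
            "duration_s": geometry.song_duration_s,
        }
    )
    total = float(onsets[-1] + geometry.song_duration_s + geometry.post_s)
    return PlaybackSchedule(
        entries=entries,
        inter_song_silence=geometry.inter_song_silence_s,
        session=session,
        subject=subject,
        total_duration=total,
    )


def _piecewise_segments(
    schedule: PlaybackSchedule,
    params: ResponseParams,
    scale: float,
    pre_s: float,
    post_s: float,
) -> list[tuple[float, float, float, str]]:
    """(start, end, rate, window) spans covering pre + playback + post.

    Inter-song silences inherit the preceding bout's condition multiplier;
    pre and post carry no condition multiplier, only the silence ratio.
    """
    bouts = schedule.bout_intervals()
    segs: list[tuple[float, float, float, str]] = []
    t_pre = max(0.0, bouts[0][0] - pre_s)
    if bouts[0][0] > t_pre:
        segs.append((t_pre, bouts[0][0], scale * params.silence_ratio, "pre"))
    for i, (b0, b1, cond) in enumerate(bouts):
        segs.append((b0, b1, scale * params.multiplier(cond), "within_song"))
        if i < len(bouts) - 1:
            nxt = bouts[i + 1][0]
            if nxt > b1:
                segs.append(
                    (
                        b1,
                        nxt,
                        scale * params.multiplier(cond) * params.silence_ratio,
                        "inter_song",
                    )
                )
    end = bouts[-1][1]
    if post_s > 0:
        segs.append((end, end + post_s, scale * params.silence_ratio, "post"))
    return segs


def simulate_calls(
    schedule: PlaybackSchedule,
    params: ResponseParams,
    bird_offset: float = 0.0,
    session: int = 1,
    rng: np.random.Generator | None = None,
    *,
    pre_s: float = 0.0,
    post_s: float = 0.0,
) -> np.ndarray:
    """Draw call onset times from the piecewise-constant Poisson process.

    Within each bout the rate is ``base_rate * multiplier[condition] *
    habituation**(session-1) * exp(bird_offset)``; outside bouts it is
    additionally multiplied by ``silence_ratio``.  Returns sorted onsets in
    schedule time, covering ``pre_s`` seconds before the first bout through
    ``post_s`` seconds after the last.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    scale = params.base_rate * params.habituation ** (session - 1) * np.exp(bird_offset)
    onsets: list[np.ndarray] = []
    for t0, t1, rate, _ in _piecewise_segments(schedule, params, scale, pre_s, post_s):
        n = rng.poisson(rate * (t1 - t0))
        if n:
            onsets.append(rng.uniform(t0, t1, size=n))
    if not onsets:
        return np.empty(0)
    return np.sort(np.concatenate(onsets))


def enforce_event_separation(onsets: np.ndarray, min_gap: float) -> np.ndarray:
    """Greedily drop events closer than ``min_gap`` to the previous kept one.

    Used when events must stay resolvable as separate calls (e.g. before
    rendering audio whose scorer merges runs across short gaps).
    """
    kept: list[float] = []
    for t in np.sort(np.asarray(onsets, dtype=float)):
        if not kept or t - kept[-1] >= min_gap:
            kept.append(float(t))
    return np.asarray(kept)


def _count_windows(onsets: np.ndarray, schedule: PlaybackSchedule) -> dict[str, int]:
    """Vectorized per-window event counts for one schedule."""
    counts = {w: 0 for w in WINDOWS}
    if len(onsets) == 0:
        return counts
    bouts = schedule.bout_intervals()
    edges = np.array([e for b0, b1, _ in bouts for e in (b0, b1)])
    idx = np.searchsorted(edges, onsets, side="right")
    counts["pre"] = int(np.sum(idx == 0))
    counts["post"] = int(np.sum(idx == len(edges)))
    inside = (idx > 0) & (idx < len(edges))
    counts["within_song"] = int(np.sum(inside & (idx % 2 == 1)))
    counts["inter_song"] = int(np.sum(inside & (idx % 2 == 0)))
    return counts


def _window_of(t: float, schedule: PlaybackSchedule) -> str:
    if t < schedule.playback_start:
        return "pre"
    if t >= schedule.playback_end:
        return "post"
    for b0, b1, _ in schedule.bout_intervals():
        if b0 <= t < b1:
            return "within_song"
    return "inter_song"


def count_events(
    onsets: np.ndarray,
    schedule: PlaybackSchedule,
    geometry: ScheduleGeometry,
    *,
    subject: str,
    session: int,
    condition: str,
) -> pd.DataFrame:
    """Tabulate simulated event onsets into count-table rows.

    Same cell structure as the scorer's table: pre / within_song /
    inter_song / post, with pre/post carrying condition ``NONE``.
    """
    n_by_window = {w: 0 for w in WINDOWS}
    for t in onsets:
        n_by_window[_window_of(t, schedule)] += 1
    song_exp = geometry.n_songs * geometry.song_duration_s
    inter_exp = (geometry.n_songs - 1) * geometry.inter_song_silence_s
    rows = [
        (NO_CONDITION, "pre", geometry.pre_s),
        (condition, "within_song", song_exp),
        (condition, "inter_song", inter_exp),
        (NO_CONDITION, "post", geometry.post_s),
    ]
    frame = pd.DataFrame(
        [
            {
                "subject": subject,
                "session": session,
                "condition": cond,
                "window": window,
                "exposure_s": exp,
                "count": n_by_window[window],
            }
            for cond, window, exp in rows
            if exp > 0 or window in ("within_song", "inter_song")
        ]
    )
    frame["rate"] = np.where(
        frame["exposure_s"] > 0, frame["count"] / frame["exposure_s"], np.nan
    )
    return frame


def simulate_experiment(
    design: ExperimentDesign,
    params: ResponseParams,
    *,
    return_events: bool = False,
):
    """Simulate every (bird, session) playback of a design.

    Returns a count table with one row per (bird, session, condition,
    window) cell; with ``return_events=True`` also a dict mapping
    ``(subject, session)`` to the simulated onset array.  Identical
    ``params.seed`` gives identical output.
    """
    root = np.random.default_rng(params.seed)
    offsets = (
        root.normal(0.0, params.bird_sd, size=design.n_birds)
        if params.bird_sd > 0
        else np.zeros(design.n_birds)
    )
    rows: list[dict] = []
    events: dict[tuple[str, int], np.ndarray] = {}
    geo = design.geometry
    schedules = {
        c: abstract_schedule(geo, c)
        for order in design.condition_orders
        for c in order
    }
    song_exp = geo.n_songs * geo.song_duration_s
    inter_exp = (geo.n_songs - 1) * geo.inter_song_silence_s
    for b in range(design.n_birds):
        subject = f"bird{b:02d}"
        for s in range(1, design.n_sessions + 1):
            condition = design.condition_for(b, s)
            schedule = schedules[condition]
            onsets = simulate_calls(
                schedule,
                params,
                bird_offset=float(offsets[b]),
                session=s,
                rng=root,
                pre_s=geo.pre_s,
                post_s=geo.post_s,
            )
            events[(subject, s)] = onsets
            n_by_window = _count_windows(onsets, schedule)
            for cond, window, exp in (
                (NO_CONDITION, "pre", geo.pre_s),
                (condition, "within_song", song_exp),
                (condition, "inter_song", inter_exp),
                (NO_CONDITION, "post", geo.post_s),
            ):
                if exp <= 0 and window in ("pre", "post"):
                    continue
                rows.append(
                    {
                        "subject": subject,
                        "session": s,
                        "condition": cond,
                        "window": window,
                        "exposure_s": exp,
                        "count": n_by_window[window],
                    }
                )
    table = pd.DataFrame(rows)
    table["rate"] = np.where(
        table["exposure_s"] > 0, table["count"] / table["exposure_s"], np.nan
    )
    if return_events:
        return table, events
    return table
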