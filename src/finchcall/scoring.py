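"""Female-call detection and windowed scoring.

In cage recordings of playback experiments the subject is much closer to the
microphone than the speaker, so her calls are substantially louder than the
song playback.  The scorer exploits exactly this level difference: it aligns
the known stimulus to the recording by envelope cross-correlation, matches
the stimulus envelope's level to the recording, and flags maximal runs where
the recording rises a margin above the expected playback-plus-noise
envelope.  Detected calls are then assigned to scoring windows — before
playback, within a song bout, between songs, after playback — from the
playback schedule, and tabulated into the per-cell count table that the
statistics operate on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .core import EPS, Waveform, rms_envelope
from .stimuli import PlaybackSchedule

__all__ = [
    "CallEvent",
    "ScoringConfig",
    "align_playback",
    "detect_calls",
    "assign_windows",
    "tabulate_counts",
    "dependent_variables",
]

WINDOWS = ("pre", "within_song", "inter_song", "post")

#: Condition label used for rows outside the playback (pre / post windows).
NO_CONDITION = "NONE"


@dataclass(frozen=True)
class CallEvent:
    """One detected call: time span, level margin, and scoring window."""

    onset: float
    offset: float
    peak_margin: float
    window: str = ""

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("call onset must precede offset")


@dataclass(frozen=True)
class ScoringConfig:
    """Detection and windowing parameters.

    ``pre_window`` / ``post_window`` are the scored spans before the first
    and after the last bout, seconds.  ``margin`` is the dB excess over the
    expected playback envelope that counts as a call.  Calls shorter than
    ``min_call_dur`` or longer than ``max_call_dur`` are discarded; runs
    separated by less than ``min_inter_call_gap`` merge into one call.
    """

    pre_window: float = 60.0
    post_window: float = 60.0
    margin: float = 10.0
    min_call_dur: float = 0.030
    max_call_dur: float = 0.300
    min_inter_call_gap: float = 0.020

    def __post_init__(self) -> None:
        for name in (
            "pre_window",
            "post_window",
            "margin",
            "min_call_dur",
            "max_call_dur",
            "min_inter_call_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_call_dur >= self.max_call_dur:
            raise ValueError("min_call_dur must be below max_call_dur")


_ENV_WINDOW = 0.005
_ENV_HOP = 0.001


def align_playback(
    recording: Waveform, stimulus: Waveform, *, min_correlation: float = 0.5
) -> tuple[float, float]:
    """Locate the stimulus inside the recording.

    Returns ``(lag_s, score)`` where ``lag_s`` maximizes the normalized
    (Pearson) cross-correlation of the 5 ms RMS envelopes on a dB scale and
    ``score`` is that peak correlation.  The dB compression keeps sparse
    loud calls from dominating the match — alignment follows the on/off
    structure of the song, not absolute energy.  Raises if the stimulus is
    longer than the recording or if the peak correlation falls below
    ``min_correlation`` (alignment failure).
    """
    if len(stimulus) > len(recording):
        raise ValueError("stimulus is longer than the recording")
    if recording.rate != stimulus.rate:
        raise ValueError("sampling rates differ")
    hop = max(1, int(round(_ENV_HOP * recording.rate)))
    _, env_r = rms_envelope(recording, _ENV_WINDOW, _ENV_HOP)
    _, env_s = rms_envelope(stimulus, _ENV_WINDOW, _ENV_HOP)
    # floor each envelope 40 dB below its peak before the log
    x = _db(np.maximum(env_r, env_r.max() * 1e-2 + EPS))
    s = _db(np.maximum(env_s, env_s.max() * 1e-2 + EPS))
    s = s - s.mean()
    n = len(s)
    num = _signal.correlate(x, s, mode="valid")  # s zero-mean: num = n*cov
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x**2)])
    win_sum = c1[n:] - c1[:-n]
    win_var = (c2[n:] - c2[:-n]) - win_sum**2 / n
    corr = num / (np.sqrt(np.maximum(win_var, 0.0) * np.sum(s**2)) + EPS)
    best = int(np.argmax(corr))
    score = float(corr[best])
    if score < min_correlation:
        raise ValueError(
            f"alignment failed: peak envelope correlation {score:.2f} < "
            f"{min_correlation}"
        )
    return best * hop / recording.rate, score


def _db(env: np.ndarray) -> np.ndarray:
    return 20.0 * np.log10(np.maximum(env, EPS))


def detect_calls(
    recording: Waveform,
    stimulus: Waveform,
    lag: float,
    cfg: ScoringConfig = ScoringConfig(),
) -> list[CallEvent]:
    """Detect calls as level excesses over the aligned playback envelope.

    The stimulus envelope is shifted by ``lag``, level-matched to the
    recording by the median envelope ratio over stimulus-active frames
    (calls are sparse, so the median tracks the playback gain, not the
    calls), floored at the recording's noise level, and subtracted in dB.
    Maximal supra-margin runs are merged across gaps shorter than
    ``min_inter_call_gap`` and filtered to the call-duration band.
    """
    hop = max(1, int(round(_ENV_HOP * recording.rate)))
    hop_s = hop / recording.rate
    _, env_r = rms_envelope(recording, _ENV_WINDOW, _ENV_HOP)
    _, env_s = rms_envelope(stimulus, _ENV_WINDOW, _ENV_HOP)
    shift = int(round(lag / hop_s))
    ref = np.zeros_like(env_r)
    src = env_s[: max(0, len(env_r) - shift)]
    ref[shift : shift + len(src)] = src
    # noise floor from the quietest decile of the recording envelope
    noise = float(np.quantile(env_r, 0.10))
    active = ref > 10.0 * noise
    if active.any():
        gain = float(np.median(env_r[active] / np.maximum(ref[active], EPS)))
        ref = ref * gain
    ref = np.maximum(ref, noise)
    excess = _db(env_r) - _db(ref)
    above = excess >= cfg.margin
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    runs = [(int(a), int(b)) for a, b in edges.reshape(-1, 2)]
    merged: list[tuple[int, int]] = []
    gap_frames = cfg.min_inter_call_gap / hop_s
    for a, b in runs:
        if merged and a - merged[-1][1] < gap_frames:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    events = []
    for a, b in merged:
        onset = a * hop_s
        offset = b * hop_s
        dur = offset - onset
        if cfg.min_call_dur <= dur <= cfg.max_call_dur:
            events.append(
                CallEvent(
                    onset=onset,
                    offset=offset,
                    peak_margin=float(np.max(excess[a:b])),
                )
            )
    return events


def assign_windows(
    events: list[CallEvent],
    schedule: PlaybackSchedule,
    cfg: ScoringConfig = ScoringConfig(),
) -> list[CallEvent]:
    """Label each call with its scoring window by onset.

    A call whose onset falls in ``[bout_start, bout_end)`` is
    ``within_song``; during the playback but outside every bout,
    ``inter_song``; before the first bout, ``pre``; at or after the last
    bout's end, ``post``.  Assignment is by onset only — a call straddling a
    bout boundary counts where it starts.  The schedule must already be in
    recording time (lag applied).
    """
    bouts = schedule.bout_intervals()
    start = schedule.playback_start
    end = schedule.playback_end
    labeled = []
    for ev in events:
        if ev.onset < start:
            window = "pre"
        elif ev.onset >= end:
            window = "post"
        else:
            window = "inter_song"
            for b0, b1, _ in bouts:
                if b0 <= ev.onset < b1:
                    window = "within_song"
                    break
        labeled.append(CallEvent(ev.onset, ev.offset, ev.peak_margin, window))
    return labeled


def _condition_of(onset: float, bouts: list[tuple[float, float, str]]) -> str:
    """Condition of the bout containing or most recently preceding ``onset``.

    The silence after a bout is attributed to that bout's condition, mirroring
    how inter-stimulus silences follow their motif condition in the playback.
    """
    current = bouts[0][2]
    for b0, b1, cond in bouts:
        if onset >= b0:
            current = cond
        else:
            break
    return current


def scheduled_cells(
    schedule: PlaybackSchedule, cfg: ScoringConfig
) -> pd.DataFrame:
    """All (condition, window) cells of a schedule with their exposures.

    ``within_song`` exposure per condition sums that condition's bout
    durations; ``inter_song`` exposure sums the silences *following* each
    bout of the condition (no silence follows the last bout); ``pre`` and
    ``post`` use the configured window lengths and carry the condition
    label ``NONE``.
    """
    bouts = schedule.bout_intervals()
    rows: list[dict] = []
    within: dict[str, float] = {}
    inter: dict[str, float] = {}
    for i, (b0, b1, cond) in enumerate(bouts):
        within[cond] = within.get(cond, 0.0) + (b1 - b0)
        if i < len(bouts) - 1:
            inter[cond] = inter.get(cond, 0.0) + (bouts[i + 1][0] - b1)
        else:
            inter.setdefault(cond, 0.0)
    rows.append(
        {"condition": NO_CONDITION, "window": "pre", "exposure_s": cfg.pre_window}
    )
    for cond in dict.fromkeys(c for _, _, c in bouts):
        rows.append(
            {"condition": cond, "window": "within_song", "exposure_s": within[cond]}
        )
        rows.append(
            {"condition": cond, "window": "inter_song", "exposure_s": inter[cond]}
        )
    rows.append(
        {"condition": NO_CONDITION, "window": "post", "exposure_s": cfg.post_window}
    )
    return pd.DataFrame(rows, columns=["condition", "window", "exposure_s"])


def tabulate_counts(
    events: list[CallEvent],
    schedule: PlaybackSchedule,
    cfg: ScoringConfig = ScoringConfig(),
    *,
    subject: str | None = None,
    session: int | None = None,
) -> pd.DataFrame:
    """Count table: one row per (subject, session, condition, window).

    Every scheduled cell is present even with zero calls.  ``rate`` is
    count / exposure in calls per second.  Within-playback calls inherit the
    condition of the bout they fall in (``within_song``) or of the bout the
    silence follows (``inter_song``); pre/post rows carry condition
    ``NONE``.
    """
    cells = scheduled_cells(schedule, cfg)
    cells.insert(0, "subject", subject if subject is not None else schedule.subject)
    cells.insert(1, "session", session if session is not None else schedule.session)
    bouts = schedule.bout_intervals()
    counts: dict[tuple[str, str], int] = {}
    for ev in events:
        if not ev.window:
            raise ValueError("events must be window-labeled (assign_windows)")
        cond = (
            NO_CONDITION
            if ev.window in ("pre", "post")
            else _condition_of(ev.onset, bouts)
        )
        counts[(cond, ev.window)] = counts.get((cond, ev.window), 0) + 1
    cells["count"] = [
        counts.get((r.condition, r.window), 0) for r in cells.itertuples()
    ]
    cells["rate"] = cells["count"] / cells["exposure_s"]
    return cells


def dependent_variables(table: pd.DataFrame) -> pd.DataFrame:
    """The three dependent variables per (subject, session, condition).

    ``total_playback_count`` (calls during the playback period, within song
    or between songs), ``within_song_count``, and ``playback_rate``
    (playback calls over playback exposure, calls/s) — the three readouts
    that condition comparisons can be run on interchangeably.
    """
    playback = table[table["window"].isin(["within_song", "inter_song"])]
    grouped = playback.groupby(["subject", "session", "condition"], sort=False)
    out = grouped.apply(
        lambda g: pd.Series(
            {
                "total_playback_count": g["count"].sum(),
                "within_song_count": g.loc[
                    g["window"] == "within_song", "count"
                ].sum(),
                "playback_exposure_s": g["exposure_s"].sum(),
            }
        ),
        include_groups=False,
    ).reset_index()
    out["playback_rate"] = out["total_playback_count"] / out["playback_exposure_s"]
    return out
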