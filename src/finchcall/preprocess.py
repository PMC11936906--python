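"""Filtering and syllable-token extraction.

Automates the by-hand steps of stimulus preparation: high-pass filtering of
song recordings at 350 Hz to remove cage rumble, amplitude-envelope
segmentation into syllables, and extraction of syllable tokens with 5 ms
raised-cosine rise/fall ramps.  Consistent ramps preserve syllable acoustics
across the inter-syllable intervals of complete silence that experimental
bouts are rebuilt with.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core import EPS, Segment, Waveform, rms_envelope

__all__ = ["SyllableToken", "highpass", "detect_syllables", "extract_syllable"]


@dataclass(frozen=True)
class SyllableToken:
    """A ramped, extracted syllable with provenance metadata.

    ``position`` is the syllable's index within its motif; ``reversed_``
    records whether the token has been spectro-temporally reversed (samples
    played backward in time).
    """

    wave: Waveform
    male_id: str = ""
    rendition_index: int = 0
    position: int = 0
    ramp: float = 0.005
    reversed_: bool = False

    @property
    def duration(self) -> float:
        return self.wave.duration

    def with_wave(self, wave: Waveform, **changes) -> "SyllableToken":
        return replace(self, wave=wave, **changes)


def highpass(wave: Waveform, cutoff: float = 350.0) -> Waveform:
    """4th-order Butterworth high-pass, single (causal) pass.

    The magnitude response is -3 dB at ``cutoff`` by construction of the
    Butterworth prototype.  Output length equals input length.
    """
    if cutoff >= wave.rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz is not below the Nyquist frequency "
            f"{wave.rate / 2:.0f} Hz"
        )
    sos = signal.butter(4, cutoff, btype="highpass", fs=wave.rate, output="sos")
    # step-matched initial state: no startup transient on a DC offset
    zi = signal.sosfilt_zi(sos) * wave.samples[0] if len(wave) else None
    if zi is None:
        return Waveform(wave.samples.copy(), wave.rate)
    out, _ = signal.sosfilt(sos, wave.samples, zi=zi)
    return Waveform(out, wave.rate)


def detect_syllables(
    wave: Waveform,
    threshold_db: float = 30.0,
    min_dur: float = 0.010,
    min_gap: float = 0.005,
    *,
    window_s: float = 0.005,
    hop_s: float = 0.001,
) -> list[Segment]:
    """Threshold the smoothed RMS envelope into syllable segments.

    The threshold sits ``threshold_db`` below the envelope peak (relative,
    so segmentation is invariant to overall level).  Supra-threshold runs
    separated by less than ``min_gap`` seconds are merged, then runs shorter
    than ``min_dur`` are dropped.  Silence yields an empty list.
    """
    if len(wave) == 0:
        raise ValueError("empty waveform")
    times, env = rms_envelope(wave, window_s, hop_s)
    peak = env.max()
    if peak < EPS:
        return []
    above = env >= peak * 10.0 ** (-threshold_db / 20.0)
    hop = max(1, int(round(hop_s * wave.rate)))
    win = max(1, int(round(window_s * wave.rate)))
    # frame index -> sample span covered by the frame
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    runs = edges.reshape(-1, 2)  # [start_frame, end_frame) pairs
    segs: list[tuple[int, int]] = []
    # map supra-threshold frame runs to sample spans via frame centers:
    # halves the boundary bias the smoothing window would otherwise add
    for f0, f1 in runs:
        s0 = max(0, int(f0) * hop + (win - hop) // 2)
        s1 = min(int(f1 - 1) * hop + (win + hop) // 2, len(wave))
        if segs and s0 - segs[-1][1] < int(round(min_gap * wave.rate)):
            segs[-1] = (segs[-1][0], s1)
        else:
            segs.append((s0, s1))
    min_samples = int(round(min_dur * wave.rate))
    return [
        Segment(s0, s1, label=f"seg{i}")
        for i, (s0, s1) in enumerate(
            (s0, s1) for s0, s1 in segs if s1 - s0 >= min_samples
        )
    ]


def extract_syllable(
    wave: Waveform,
    seg: Segment,
    ramp: float = 0.005,
    *,
    male_id: str = "",
    rendition_index: int = 0,
    position: int = 0,
) -> SyllableToken:
    """Slice a segment and apply raised-cosine on/off ramps.

    The ramp rises from 0 to 1 over ``ramp`` seconds (reaching full interior
    amplitude exactly at the ramp length); interior samples are untouched.
    The cosine taper is symmetric under time reversal, so tokens can be
    reversed after extraction without changing their edge shape.

    An edge that is already tapered is left alone: if the edge span's RMS is
    well below the interior RMS (as it is after a previous extraction), the
    ramp is not re-applied, making extraction idempotent on its own output.
    """
    if seg.end > len(wave):
        raise ValueError("segment extends past the waveform")
    n = seg.n_samples
    n_ramp = int(round(ramp * wave.rate))
    if n < 2 * n_ramp:
        raise ValueError(
            f"segment of {n} samples is shorter than twice the ramp "
            f"({2 * n_ramp} samples); need >= 2 x {ramp * 1e3:.1f} ms"
        )
    x = wave.samples[seg.start : seg.end].copy()
    if n_ramp > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        interior = x[n_ramp:-n_ramp] if n > 2 * n_ramp else x
        interior_rms = np.sqrt(np.mean(interior**2)) + EPS
        # a flat edge has RMS ~ interior; a cosine-ramped one ~ 0.61 x interior
        if np.sqrt(np.mean(x[:n_ramp] ** 2)) / interior_rms >= 0.8:
            x[:n_ramp] *= r
        if np.sqrt(np.mean(x[-n_ramp:] ** 2)) / interior_rms >= 0.8:
            x[-n_ramp:] *= r[::-1]
    return SyllableToken(
        wave=Waveform(x, wave.rate),
        male_id=male_id,
        rendition_index=rendition_index,
        position=position,
        ramp=ramp,
    )
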