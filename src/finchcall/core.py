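"""Shared audio primitives: the :class:`Waveform` container, the dBFS level
convention, RMS envelopes, and WAV / segment-CSV round-trips.

Level convention
----------------
All digital levels are dBFS referenced to the RMS of a full-scale sine
(RMS = 1/sqrt(2)).  A waveform whose RMS equals ``2**-0.5`` sits at 0 dBFS.
Sound-pressure levels are never modelled; only level *differences* between
mixture components are controlled, which is all the call scorer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

#: RMS of a full-scale (peak 1) sine wave — the 0 dBFS reference.
FULL_SCALE_SINE_RMS: float = 2.0 ** -0.5

#: Default sampling rate for all synthesized stimuli, in Hz.
DEFAULT_RATE: int = 44_100

EPS = 1e-12


def dbfs_to_rms(level_db: float) -> float:
    """Target RMS amplitude for a level in dBFS."""
    return FULL_SCALE_SINE_RMS * 10.0 ** (level_db / 20.0)


def rms_to_dbfs(rms: float) -> float:
    """Level in dBFS of an RMS amplitude (``-inf`` for silence)."""
    return 20.0 * np.log10(max(rms, EPS) / FULL_SCALE_SINE_RMS)


@dataclass(frozen=True)
class Waveform:
    """Mono sampled audio.

    Parameters
    ----------
    samples
        Amplitude sequence, nominally within [-1, 1].
    rate
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Waveform is mono: samples must be 1-D")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Waveform samples must be finite")
        if self.rate <= 0:
            raise ValueError("Sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.rate

    @property
    def rms(self) -> float:
        if self.samples.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))

    @property
    def level_dbfs(self) -> float:
        return rms_to_dbfs(self.rms)

    def scaled_to(self, level_db: float) -> "Waveform":
        """Return a copy scaled to an exact RMS level in dBFS."""
        rms = self.rms
        if rms < EPS:
            raise ValueError("cannot scale silence to a target level")
        return Waveform(self.samples * (dbfs_to_rms(level_db) / rms), self.rate)

    def seconds_to_samples(self, t: float) -> int:
        return int(round(t * self.rate))


def silence(duration_s: float, rate: int) -> Waveform:
    return Waveform(np.zeros(int(round(duration_s * rate))), rate)


def concatenate(waves: list[Waveform]) -> Waveform:
    if not waves:
        raise ValueError("nothing to concatenate")
    rates = {w.rate for w in waves}
    if len(rates) > 1:
        raise ValueError(f"mixed sampling rates: {sorted(rates)}")
    return Waveform(np.concatenate([w.samples for w in waves]), waves[0].rate)


def rms_envelope(
    wave: Waveform, window_s: float = 0.005, hop_s: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """Short-time RMS envelope.

    Returns ``(times, env)`` where ``times[i]`` is the *center* of frame ``i``
    in seconds and ``env[i]`` its RMS amplitude.  Frames start at sample 0 and
    advance by ``hop_s``; the trailing partial frame is kept.
    """
    win = max(1, int(round(window_s * wave.rate)))
    hop = max(1, int(round(hop_s * wave.rate)))
    x2 = wave.samples**2
    csum = np.concatenate([[0.0], np.cumsum(x2)])
    starts = np.arange(0, max(1, len(wave) - win + hop), hop)
    ends = np.minimum(starts + win, len(wave))
    starts = np.minimum(starts, ends - 1)
    env = np.sqrt((csum[ends] - csum[starts]) / (ends - starts))
    times = (starts + ends) / 2.0 / wave.rate
    return times, env


def write_wav(path: str | Path, wave: Waveform) -> None:
    """Write a mono float32 RIFF WAV (no quantization of test signals)."""
    wavfile.write(str(path), wave.rate, wave.samples.astype(np.float32))


def read_wav(path: str | Path) -> Waveform:
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype.kind == "i":  # integer PCM -> [-1, 1]
        data = data / float(-np.iinfo(data.dtype).min)
    return Waveform(data.astype(np.float64), int(rate))


@dataclass(frozen=True)
class Segment:
    """Half-open sample interval ``[start, end)`` with a text label."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment [{self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def duration(self, rate: int) -> float:
        return self.n_samples / rate


def segments_to_frame(segments: list[Segment], rendition_index: int | None = None) -> pd.DataFrame:
    rows = [
        {"label": s.label, "start_sample": s.start, "end_sample": s.end}
        for s in segments
    ]
    frame = pd.DataFrame(rows, columns=["label", "start_sample", "end_sample"])
    if rendition_index is not None:
        frame["rendition_index"] = rendition_index
    return frame


def write_segments_csv(path: str | Path, segments: list[Segment], **meta) -> None:
    segments_to_frame(segments, **meta).to_csv(path, index=False)


def read_segments_csv(path: str | Path) -> list[Segment]:
    frame = pd.read_csv(path)
    return [
        Segment(int(r.start_sample), int(r.end_sample), str(r.label))
        for r in frame.itertuples()
    ]
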