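"""Synthetic zebra-finch-like song and cage-recording mixtures.

Real zebra finch syllables are harmonic stacks with fast frequency and
amplitude modulation.  The generator keeps only the features the downstream
pipeline actually exercises: a harmonic series on a linearly swept
fundamental (an FM sweep is direction-dependent, so spectro-temporal
reversal is a *real* manipulation of these signals, unlike a pure tone),
optional broadband noise, per-rendition jitter of duration / pitch / level,
and cage-recording mixtures in which female calls are louder than the song
playback — the level geometry the call scorer relies on.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    DEFAULT_RATE,
    Segment,
    Waveform,
    concatenate,
    dbfs_to_rms,
    silence,
)

__all__ = [
    "SyllableSpec",
    "MotifSpec",
    "RenditionJitter",
    "synth_syllable",
    "synth_motif_rendition",
    "synth_call",
    "synth_recording",
    "example_motif_spec",
]


@dataclass(frozen=True)
class SyllableSpec:
    """Parameters of one synthetic syllable voice.

    duration
        Seconds, > 0.
    f0
        Fundamental at syllable onset, Hz.
    n_harmonics
        Number of harmonic partials (>= 1).
    harmonic_rolloff
        Attenuation per successive harmonic, dB (>= 0 rolls off).
    fm_excursion
        Linear sweep of the fundamental from ``f0`` at onset to
        ``f0 + fm_excursion`` at offset, Hz.  Nonzero by default so that
        time reversal changes the signal.
    noise_fraction
        Fraction of signal *power* contributed by broadband noise, in [0, 1].
    level
        Target RMS level in dBFS (<= 0).
    """

    duration: float = 0.080
    f0: float = 600.0
    n_harmonics: int = 5
    harmonic_rolloff: float = 6.0
    fm_excursion: float = 200.0
    noise_fraction: float = 0.05
    level: float = -20.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must lie in [0, 1]")
        if self.level > 0:
            raise ValueError("level is dBFS and must be <= 0")


@dataclass(frozen=True)
class MotifSpec:
    """An ordered syllable sequence with inter-syllable gaps (seconds)."""

    syllables: tuple[SyllableSpec, ...]
    gaps: tuple[float, ...]

    def __post_init__(self) -> None:
        syllables = tuple(self.syllables)
        gaps = tuple(float(g) for g in self.gaps)
        if len(syllables) < 1:
            raise ValueError("a motif needs at least one syllable")
        if len(gaps) != len(syllables) - 1:
            raise ValueError("need exactly len(syllables) - 1 gaps")
        if any(g < 0 for g in gaps):
            raise ValueError("gaps must be non-negative")
        object.__setattr__(self, "syllables", syllables)
        object.__setattr__(self, "gaps", gaps)

    @property
    def n_syllables(self) -> int:
        return len(self.syllables)


@dataclass(frozen=True)
class RenditionJitter:
    """Rendition-to-rendition variation of syllable acoustics.

    ``duration_cv`` and ``f0_cv`` are coefficients of variation of
    multiplicative log-normal jitter (mean-one, so jittered durations and
    fundamentals stay positive and unbiased); ``level_sd`` is an additive
    Gaussian offset in dB.
    """

    duration_cv: float = 0.05
    f0_cv: float = 0.02
    level_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_cv < 0 or self.f0_cv < 0 or self.level_sd < 0:
            raise ValueError("jitter magnitudes must be non-negative")


def _lognormal_multiplier(rng: np.random.Generator, cv: float) -> float:
    # mean-one log-normal: sigma^2 = log(1 + cv^2) gives sample CV == cv
    sigma = np.sqrt(np.log1p(cv**2))
    return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))


def _edge_ramp(n: int, n_ramp: int) -> np.ndarray:
    """Raised-cosine on/off taper of ``n_ramp`` samples at each edge."""
    env = np.ones(n)
    if n_ramp <= 0:
        return env
    n_ramp = min(n_ramp, n // 2)
    r = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    env[:n_ramp] = r
    env[-n_ramp:] = r[::-1]
    return env


def synth_syllable(
    spec: SyllableSpec,
    rate: int = DEFAULT_RATE,
    *,
    ramp: float = 0.005,
    seed: int = 0,
) -> Waveform:
    """Render one syllable: harmonic stack on a linear FM sweep plus noise.

    The output has ``round(duration * rate)`` samples, edge tapers of
    ``ramp`` seconds, RMS exactly at ``spec.level`` dBFS and peak <= 1.

    Raises
    ------
    ValueError
        If ``rate < 2 * (f0 * n_harmonics + fm_excursion)`` — the highest
        harmonic would alias across the Nyquist frequency ``rate / 2``.
    """
    f_top = spec.f0 * spec.n_harmonics + abs(spec.fm_excursion)
    if rate < 2.0 * f_top:
        raise ValueError(
            f"rate {rate} Hz cannot represent harmonics up to {f_top:.0f} Hz: "
            f"Nyquist bound requires rate >= {2.0 * f_top:.0f} Hz"
        )
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate
    # phase of a linear sweep f0 -> f0 + fm_excursion over the duration
    phase = 2.0 * np.pi * (spec.f0 * t + 0.5 * spec.fm_excursion * t**2 / spec.duration)
    x = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        amp = 10.0 ** (-(k - 1) * spec.harmonic_rolloff / 20.0)
        x += amp * np.sin(k * phase)
    x /= max(np.sqrt(np.mean(x**2)), 1e-12)
    if spec.noise_fraction > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(n)
        noise /= np.sqrt(np.mean(noise**2))
        x = np.sqrt(1.0 - spec.noise_fraction) * x + np.sqrt(spec.noise_fraction) * noise
    x *= _edge_ramp(n, int(round(ramp * rate)))
    # exact level after tapering
    x *= dbfs_to_rms(spec.level) / np.sqrt(np.mean(x**2))
    peak = np.max(np.abs(x))
    if peak > 1.0:
        warnings.warn(
            f"syllable at {spec.level:.1f} dBFS would peak at {peak:.2f}; "
            "rescaled to full scale",
            stacklevel=2,
        )
        x /= peak
    return Waveform(x, rate)


def _position_label(i: int) -> str:
    letters = string.ascii_lowercase
    label = ""
    i0 = i
    while True:
        label = letters[i0 % 26] + label
        i0 = i0 // 26 - 1
        if i0 < 0:
            return label


def synth_motif_rendition(
    motif: MotifSpec,
    jitter: RenditionJitter,
    rendition_index: int,
    rate: int = DEFAULT_RATE,
) -> tuple[Waveform, list[Segment]]:
    """Render one motif rendition with per-syllable jitter.

    Syllables are labelled ``a, b, c, ...`` by position.  The returned
    segments give each syllable's half-open sample interval in the motif
    waveform.  Output is a pure function of ``(motif, jitter.seed,
    rendition_index, rate)``; with all jitter magnitudes zero, every
    rendition index yields sample-identical audio.
    """
    if rendition_index < 0:
        raise ValueError("rendition_index must be >= 0")
    rng = np.random.default_rng(
        np.random.SeedSequence([jitter.seed & 0x7FFFFFFF, rendition_index])
    )
    pieces: list[Waveform] = []
    segments: list[Segment] = []
    cursor = 0
    for i, syl in enumerate(motif.syllables):
        dur_mult = _lognormal_multiplier(rng, jitter.duration_cv)
        f0_mult = _lognormal_multiplier(rng, jitter.f0_cv)
        level_off = float(rng.normal(0.0, jitter.level_sd)) if jitter.level_sd > 0 else 0.0
        jittered = SyllableSpec(
            duration=syl.duration * dur_mult,
            f0=syl.f0 * f0_mult,
            n_harmonics=syl.n_harmonics,
            harmonic_rolloff=syl.harmonic_rolloff,
            fm_excursion=syl.fm_excursion * f0_mult,
            noise_fraction=syl.noise_fraction,
            level=min(syl.level + level_off, 0.0),
        )
        # noise realisation tied to (seed, position), not rendition, so the
        # no-jitter degenerate case is exactly rendition-invariant
        wave = synth_syllable(
            jittered, rate, seed=int(np.random.SeedSequence(
                [jitter.seed & 0x7FFFFFFF, 7919, i]).generate_state(1)[0] & 0x7FFFFFFF)
        )
        segments.append(Segment(cursor, cursor + len(wave), _position_label(i)))
        pieces.append(wave)
        cursor += len(wave)
        if i < len(motif.gaps):
            gap = silence(motif.gaps[i], rate)
            pieces.append(gap)
            cursor += len(gap)
    return concatenate(pieces), segments


def synth_call(
    level: float,
    rate: int = DEFAULT_RATE,
    *,
    duration: float = 0.100,
    f0: float = 550.0,
    n_harmonics: int = 4,
) -> Waveform:
    """Female-call stand-in: a 100 ms harmonic burst around 550 Hz.

    Only its level contrast with the playback matters to the scorer.
    """
    spec = SyllableSpec(
        duration=duration,
        f0=f0,
        n_harmonics=n_harmonics,
        harmonic_rolloff=8.0,
        fm_excursion=-80.0,
        noise_fraction=0.0,
        level=level,
    )
    return synth_syllable(spec, rate)


def synth_recording(
    playback: Waveform,
    playback_level: float,
    call_events: list[tuple[float, float, float]],
    noise_level: float = -70.0,
    seed: int = 0,
) -> Waveform:
    """Mix a cage recording: scaled playback + female calls + background noise.

    Parameters
    ----------
    playback
        The stimulus waveform; the recording has the same length.
    playback_level
        RMS level of the playback *component* within the mixture, dBFS
        (measured over its non-silent extent).
    call_events
        ``(onset_s, duration_s, level_dbfs)`` triples.  Call levels must
        exceed ``playback_level`` — the recording geometry in which the
        female is nearer the microphone than the speaker, which is the
        premise the level-difference scorer depends on.
    noise_level
        RMS level of the Gaussian background, dBFS.
    seed
        Noise realisation seed; identical seeds give identical samples.
    """
    for onset, dur, lev in call_events:
        if lev <= playback_level:
            raise ValueError(
                f"call at {onset:.3f} s has level {lev:.1f} dBFS, not above "
                f"the playback level {playback_level:.1f} dBFS"
            )
        if onset < 0 or onset + dur > playback.duration + 1e-9:
            raise ValueError(
                f"call at {onset:.3f} s (+{dur:.3f} s) extends past the "
                f"{playback.duration:.3f} s recording"
            )
    rate = playback.rate
    mix = np.zeros(len(playback))
    if playback.rms > 0:
        mix += playback.scaled_to(playback_level).samples
    for onset, dur, lev in call_events:
        call = synth_call(lev, rate, duration=dur)
        i0 = int(round(onset * rate))
        mix[i0 : i0 + len(call)] += call.samples[: len(mix) - i0]
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(mix))
    noise *= dbfs_to_rms(noise_level) / np.sqrt(np.mean(noise**2))
    mix += noise
    peak = np.max(np.abs(mix)) if len(mix) else 0.0
    if peak > 1.0:
        warnings.warn(
            f"recording mixture peaks at {peak:.2f}; clipped to full scale",
            stacklevel=2,
        )
        mix = np.clip(mix, -1.0, 1.0)
    return Waveform(mix, rate)


def example_motif_spec(
    n_syllables: int = 4,
    gap_s: float = 0.020,
    level: float = -20.0,
) -> MotifSpec:
    """A four-syllable motif in the style of a zebra finch motif 'a b c d'.

    Syllables differ in fundamental, sweep direction and length so that
    shuffling and reversal are acoustically distinct manipulations.
    """
    bank = [
        SyllableSpec(duration=0.070, f0=550.0, fm_excursion=250.0, level=level),
        SyllableSpec(duration=0.090, f0=700.0, fm_excursion=-300.0, level=level),
        SyllableSpec(duration=0.060, f0=480.0, fm_excursion=180.0, n_harmonics=6, level=level),
        SyllableSpec(duration=0.110, f0=620.0, fm_excursion=-220.0, n_harmonics=4, level=level),
        SyllableSpec(duration=0.080, f0=820.0, fm_excursion=260.0, n_harmonics=4, level=level),
        SyllableSpec(duration=0.075, f0=500.0, fm_excursion=-150.0, level=level),
    ]
    syllables = tuple(bank[i % len(bank)] for i in range(n_syllables))
    gaps = tuple(gap_s for _ in range(max(0, n_syllables - 1)))
    return MotifSpec(syllables=syllables, gaps=gaps)
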