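# Methods

This note records the models, conventions, parameter choices and known
limitations behind `finchcall`, in the spirit of a package methods appendix.

## Signal conventions

All audio is mono, float64 in memory and float32 WAV on disk (so round
trips are lossless), synthesized at 44.1 kHz by default.  Levels are dBFS
referenced to the RMS of a full-scale sine (RMS = 1/√2); only level
*differences* between mixture components are meaningful, and the scorer
relies exclusively on them.  Sound-pressure calibration is not modelled.
Sample indices are 0-based with half-open `[start, end)` segments;
durations are stored in seconds and converted by rounding to the nearest
sample.

## Synthetic song

A syllable is a stack of `n_harmonics` partials on a fundamental that
sweeps linearly from `f0` to `f0 + fm_excursion` over the syllable, with
`harmonic_rolloff` dB attenuation per partial and an optional broadband
noise component mixed by power fraction.  The linear FM sweep is the
essential ingredient: a swept harmonic stack is direction-dependent, so
spectro-temporal reversal genuinely changes the signal, whereas a pure tone
would make REVERSAL a no-op.  Default syllable specs therefore always carry
nonzero `fm_excursion`.  The stand-in for a female call is a 100 ms
harmonic burst around 550 Hz; only its level contrast with the playback
matters to the scorer.

Rendition-to-rendition jitter multiplies syllable duration and fundamental
by mean-one log-normal factors (σ² = log(1+cv²), so the sample CV equals
the nominal CV and jittered values stay positive) and adds a Gaussian dB
offset to level.  All generators are pure functions of (spec, seed): the
jitter stream is derived from `(seed, rendition_index)` and each
syllable's noise realisation from `(seed, position)` only, so the
zero-jitter case is exactly rendition-invariant.

No attempt is made to imitate any particular male's syllables; the
generator's defaults are chosen to exercise the pipeline (distinct
fundamentals, alternating sweep directions, realistic 60–110 ms durations
and 20 ms gaps), not to match real spectrograms.

## Preprocessing

The high-pass is a 4th-order Butterworth at 350 Hz, applied in a single
causal pass with step-matched initial conditions (a DC offset produces no
startup transient); its −3 dB point is the design cutoff by construction.
Syllable detection thresholds the 5 ms / 1 ms-hop RMS envelope at a level
relative to the envelope peak (default 30 dB below), merges supra-threshold
runs separated by under 5 ms and drops runs under 10 ms.  Frame runs are
mapped to sample spans via frame centers, which keeps boundaries within
about ±3 ms of ground truth; the envelope window sets the resolution
limit — inter-syllable gaps at or below ~5 ms are smeared shut and cannot
be recovered, so reliable segmentation needs gaps comfortably above the
window (the test suite uses ≥15 ms).

Token extraction applies raised-cosine on/off ramps (default 5 ms, the
value needed to preserve syllable features across silent inter-syllable
intervals).  The ramp rises 0→1 over exactly the ramp length and the taper
is time-symmetric, so reversal after extraction leaves edge shapes
unchanged.  An edge whose RMS is already well below the interior RMS
(under 0.8×, as after a previous extraction) is left alone, making
extraction idempotent on its own output rather than squaring the taper.

## Stimulus construction

All six conditions share one positional timing grid: syllable slot *j*
always carries the reference rendition's gap *j* after it, so REVERSAL and
SHUFFLED leave every onset unchanged and all conditions of a template have
identical total duration (RENDITION aside, whose bank tokens carry natural
duration jitter).  SHUFFLED draws a fresh uniform permutation per motif and
redraws on the identity (with >1 syllable), so the condition always differs
from FIXED — the natural-order exclusion is this package's choice where the
field's usage is ambiguous.  RENDITION maps motif *i* to bank rendition
*i mod K*, i.e. consecutive natural renditions build the bout.
FIRST/LAST-MOTIF REVERSAL reverse every token of the first/last motif only;
with 8 motifs per bout exactly 1/8 of syllable slots are manipulated.

Bout randomness comes from one seed, hierarchically split per motif, and
playlists record absolute onsets in a schedule (JSON-serialisable), so any
stimulus regenerates exactly from its metadata.  Inter-song silence is
placed between songs only; lead-in/lead-out silences are separate
parameters, since published design tables typically leave the trailing
silence unspecified.

## Call scoring

Alignment maximizes the sliding Pearson correlation of the recording's and
stimulus's 5 ms RMS envelopes on a dB scale (floored 40 dB below each
envelope's peak).  The dB compression makes the match follow the song's
on/off structure rather than absolute energy, so sparse loud calls shift
the estimated lag by well under 10 ms; a peak correlation below 0.5 is an
alignment failure.

Detection level-matches the aligned stimulus envelope to the recording by
the median envelope ratio over stimulus-active frames (calls are sparse, so
the median tracks the playback gain), floors it at the recording's
10th-percentile envelope (the noise level), and takes maximal runs where
the recording exceeds this reference by the margin (default 10 dB).  Runs
merge across gaps under 20 ms and must last 30–300 ms.  The defaults are
chosen so that synthetic ground truth is recovered exactly when calls sit
at least margin + 5 dB above the playback and are well separated; all are
configuration, not constants, because the field's by-eye scoring criterion
has no unique algorithmic counterpart.

Windows are assigned by call onset alone (a call straddling a bout
boundary counts where it starts): within-song on `[bout_start, bout_end)`,
inter-song elsewhere during the playback, pre/post outside it.  The count
table carries one row per scheduled (condition, window) cell even at zero
calls.  Inter-song exposure is attributed to the *preceding* bout's
condition (each silence follows its motif condition); pre/post rows carry
the condition label `NONE`.  Pre-playback baseline subtraction is not
applied by default but the pre-window rate is available in the table.
Calls closer than the envelope window to a boundary are intrinsically
ambiguous for any level-based scorer; the closure battery therefore only
asserts exact recovery for calls clear of boundaries.

## Behavioral simulation

Calling is a piecewise-constant-rate Poisson process: during a bout,
rate = `base_rate × condition_multiplier × habituation^(session−1) ×
exp(bird_offset)`; outside bouts the rate is additionally multiplied by
`silence_ratio` (inter-song silences inherit the preceding bout's condition
multiplier; pre/post carry none).  Bird offsets are N(0, bird_sd²) on the
log scale — the random-intercept structure a mixed count model assumes.
Habituation is geometric across sessions: a single parameter capturing the
monotone session-to-session decline seen in repeated playback without
asserting any finer functional form.  Within-bout rate is constant; no
within-bout dynamics are modelled, and the simulator cannot say whether
habituation attaches to a male's identity or to the paradigm — it exposes
only a session index.

Default generating values used throughout the calibration batteries:
`base_rate` 0.5 calls/s during song (a robust responder's within-song
rate), `silence_ratio` 0.1, REVERSAL multiplier 0.1 (calling to reversals
is near-absent), habituation 0.65 per session (a strong, monotone
decline), `bird_sd` 0.5 (birds ranging from non-callers to strong
callers).

## Statistics

*Exact two-rate test*: conditional on n = x₁+x₂, x₁ ~ Binomial(n,
T₁/(T₁+T₂)) under the null; the two-sided p sums the probabilities of all
outcomes no more probable than observed (minimum-likelihood convention,
stated explicitly because several two-sided conventions exist; ties are
accepted within 1e−9 relative slack).  Both counts zero gives p = 1 and an
undefined ratio.

*Permutation test*: counts and exposures aggregate per (bird, condition);
condition labels permute within bird.  With 2^n_birds ≤ `n_perm` all
assignments are enumerated and p = #{|T*| ≥ |T_obs|}/2^n_birds (exact);
otherwise p = (1+#{|T*| ≥ |T_obs|})/(1+n_perm).  The default statistic is
the mean within-bird rate difference; a pooled log-rate-ratio (with a 0.5
continuity guard) is also available.  The test is implemented for
two-condition contrasts, mirroring pairwise usage; multi-condition tables
are compared pairwise.

*Poisson regression*: log-link ML via IRLS, converging when the largest
coefficient update is below 1e−8 (at most 50 iterations).  Bird
heterogeneity is handled by bird indicator columns — fixed effects, not
random intercepts; mixed-model estimation is deliberately out of scope, and
the permutation test provides the assumption-free companion.  Likelihood
ratios for a named term come from refitting without its columns.
Rank-deficient designs are rejected naming the collinear columns.  An
all-zero response stratum drives its coefficient to −∞; the fit clamps at
−30 on the log scale (a rate of ~1e−13 calls/s, numerically zero) and sets
a `boundary` flag instead of raising.  Pairwise contrasts default to Holm
adjustment (assumption-free family-wise control), raw p-values retained.

*Habituation trend*: per-(bird, session) totals regressed on session index
with bird intercepts and log-exposure offset; exactly geometric data
recovers the log decay to machine precision.

## Calibration batteries and problem sizes

The acceptance script and test suite size their simulations for a desk
machine: closure scenarios run at 22.05 kHz with three 2-motif songs,
1.5 s inter-song silences and 1 s pre/post windows (≈12 s of audio each,
100 scenarios); recovery batteries use eight birds, four sessions and
eight 6.4 s songs per playback (51.2 s of song exposure per session, the
long-bout regime) for 200 replicates, and the type-I battery 2000 null
replicates.  With 2⁸ enumerable label assignments the permutation test's
attainable p-values are multiples of 2/256, so its exact type-I rate at
α = 0.05 is 12/256 ≈ 0.047 — slightly conservative by construction.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* real data would have —
harmonic syllables with rendition jitter, recordings where calls outlevel
playback, Poisson-like counts with bird heterogeneity and habituation — but
none of the messiness: no cage noise transients, wing fluffs or male
calls, no overlapping or graded calls, no room acoustics, no rate drift
within a session.  Exact pipeline closure on synthetic scenarios therefore
validates the bookkeeping (alignment, thresholds, windows, exposures) and
the statistics' calibration, not detection performance on field
recordings, where the by-eye criterion the scorer replaces remains the
benchmark.
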