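# Methods

This note documents the models, parameter choices and known limitations
of the pipeline: what exactly is synthesized, how the simulated
protocol and observers work, and what passing tests do and do not show
about real experiments.

## Nonsense-word inventory

Two disjoint 12-word lists are built from six CV syllables each; every
syllable appears in four words of its list, twice initially and twice
finally, so syllable identity is uninformative about the stress
pattern.  The published table of words lays the two lists out in
side-by-side columns; reading its flowed text row-wise interleaves the
lists.  The transcription frozen in `lexicon.py` assigns alternate
words to alternate sets, which is the only assignment under which all
structural constraints hold simultaneously (6 syllables per set, 2×
initial + 2× final usage, disjoint inventories).  `validate_set()`
checks every constraint and is itself under test, so any future edit
that breaks the structure is caught immediately.

## Stimulus synthesis

The original stimuli were edited recordings of a human speaker.  This
package ships no recordings; instead each syllable is synthesized from
scratch with a source–filter model:

* **Voiced source** — an impulse train whose instantaneous f₀ follows
  the specified contour (flat 194 Hz when unstressed; a linear ramp
  from 194 Hz to the drawn peak, reaching the peak at syllable end,
  when stressed), shaped by two one-pole low-pass filters (glottal
  spectral tilt) and DC-blocked.
* **Vowel filter** — a cascade of three second-order resonators at
  F1–F3 targets per IPA vowel (typical adult-female values, consistent
  with the 194 Hz base f₀; bandwidths 90/120/170 Hz).  Diphthongs
  ([eɪ], [oʊ]) are rendered as a crossfade between two target frames.
  The table is exportable/importable as CSV for customization.
* **Consonant onsets** — stylized: voiceless stops as silence + a
  band-filtered burst, voiced stops with a low murmur, fricatives as
  band-passed noise (voiced ones mixed with murmur), nasals/liquids/
  glides as voiced sonorants through their own resonator targets.
  Onsets occupy min(60 ms, 20 % of the syllable).
* **Assembly** — consonant and vowel parts are crossfaded over 10 ms,
  5 ms raised-cosine edge ramps suppress concatenation clicks, and the
  whole syllable is scaled to the target RMS (ramps applied first so
  the RMS contract is exact).  Words concatenate their two syllables
  with zero gap.  Output is mono 16-bit PCM WAV at 44.1 kHz; all
  content sits below ~5 kHz.

Contracts (each under test): duration exact to one sample; RMS within
1 % relative; f₀ of flat-contour syllables within 2 Hz; the terminal
analysis frame of a rising contour within 3 Hz of the ramp's mean over
that frame.  Consonant noise is seeded from a hash of the syllable and
its drawn parameters, so a seeded bank regenerates bit-identically.

Randomized cue values (stressed f₀ peak; unstressed duration and RMS)
are drawn independently per syllable occurrence.  Whether the original
design shared draws within a word is not documented; independence is
assumed.  Likewise, vowel-quality neutralization substitutes the full
vowel while leaving duration a separate axis — the two are independent
manipulations here.

### f₀ estimation

The QC pitch tracker is frame-wise normalized autocorrelation (40 ms
frames, 10 ms hop, search range 120–350 Hz).  The biased
autocorrelation's linear taper is divided out before peak picking
(otherwise estimates sit ~1 Hz low), the earliest local maximum within
95 % of the global maximum guards against octave-down errors, and
parabolic interpolation refines the lag.  Frames below 5 % of the
waveform's overall RMS, or with a peak below 0.35, are flagged
unvoiced.

## Protocol engine

Six phases in fixed order: preliminary (single syllables, sound vs.
silence, 5/5 per block of 10), discrimination training (trochee/iamb
5/5 per block, S+ reinforced 100 %), pre-testing (S+ reinforced 85 %,
to blur the later contrast with unreinforced probes), the 120-trial
novel-word test, a second pre-test, and the 240-trial absent-cue test.
Both tests insert 2 unreinforced probes per block of 10 (20 %), with 4
trained S+ and 4 trained S−; each novel-word probe (12 words × 2
patterns) occurs exactly once, as does each of the 48 cue-manipulation
probes (3 exemplars × 8 manipulations × 2 patterns).  Trained S+
trials remain reinforced at 85 % during tests.

Progression criteria:

* **Trial-based subjects (humans)** — phase-cumulative DR ≥ 0.8 after
  at least 10 trials, with maxima of 100 (preliminary), 150
  (discrimination) and 50 (pre-testing) trials.  "Overall DR" is read
  as cumulative over the phase rather than a sliding window; a window
  variant would pass slightly different subjects but the cumulative
  reading matches the phrase "minimum of 10 trials with an overall
  discrimination ratio".
* **Sessioned subjects (budgerigars)** — session lengths are Poisson
  with mean 103 trials, truncated below at 40.  Criteria: 2 sessions
  with DR ≥ 0.8 (preliminary), 4 consecutive such sessions
  (discrimination), ≥ 3 sessions with the last 2 at criterion
  (pre-test 1), 1 session (pre-test 2).  A phase is failed — and the
  subject excluded — after 150 sessions without criterion, matching
  the practice of stopping non-learners after >130 sessions.  Fixed-
  length tests are resumable across session boundaries (a subject may
  split the 240-trial test over two sessions).

The birds' preliminary touchscreen shape-training contains no auditory
computation and is recorded only as configuration, not simulated.

Reinforcement: responding to S+ earns reward with the trial's
reinforcement probability (+10 points or food); responding to S−
earns a penalty (−10 points + 5 s delay, or a 30 s delay); probes and
withheld responses produce no feedback, hence no learning.

Within preliminary blocks the positions of sound trials are random but
the syllable sequence itself follows the shuffle-without-replacement
cycle, so the "every variant once before any repeats" property holds
in presentation order.  Probe positions within test blocks are
unconstrained beyond the 2-per-10 composition.

## Observer model

Perception: for syllable slot *i* with normalized cue vector
`x_i = (pitch, amplitude, duration, vowel)`,

    s_i = Σ_c w_c · x_ic + ε_i,   ε_i ~ N(0, σ²) i.i.d.

The perceived pattern is trochaic iff `s_1 > s_2`; exact ties (possible
only in noiseless, cue-free configurations) are resolved by a fair
coin and flagged ambiguous.  Cue normalization puts all cues on
comparable [0, 1] scales so weights are interpretable: pitch in
semitones above 194 Hz divided by the maximum excursion (12·log₂(280/194)
≈ 6.35 st); amplitude as 1 + dB re 0.1 / 10 (so the stressed target is
1 and the 10 dB-down floor is 0); duration as (d − 0.3)/0.2; vowel
fullness binary.  Percepts are computed from stimulus parameters, not
audio, which makes protocol simulation fast; an audio-measurement path
(`PerceptDescriptor.from_audio`) exists and is tested to agree within
measurement tolerance.

Response: go probability

    p(go) = min( lapse·bias + (1 − lapse)·a_eff , ceiling ),
    a_eff = (1 − ν·atyp)·A[percept] + ν·atyp·bias

where `A` is the learned percept→go association, `atyp` is the
fraction of neutralized cues in the stimulus (0 for training and
novel-word stimuli, 0.25 for one-cue-removed probes, 0.75 for
single-cue probes) and ν the observer's novelty sensitivity.  The
novelty term models disrupted responding to stimuli that sound unlike
anything reinforced in training; it is what allows a spread-weight
observer to discriminate one-cue-removed probes yet sit at chance on
single-cue probes — a purely additive cue model cannot produce that
combination, because the three-cue signal is at most about three times
the single-cue signal, so any weights strong enough to pass the
removed-cue conditions would also push single-cue performance above
chance.

Learning: a delta rule on the binary percept→go association,
`A ← A + λ(target − A)` with target 1 after reward and 0 after penalty;
probes and no-feedback trials leave the state untouched, so
associations remain in [0, 1].  Learning over abstract percepts (not
raw cues or word identities) is the simplest mechanism that yields both
acquisition-to-criterion and transfer to novel words.  Timeouts are
modeled as 1 − p(go); latencies are decorative draws.

### Presets

Presets encode qualitative species signatures; the experimental data
cannot constrain σ, λ or ν, and no subject-level fitting is implied.

| parameter | human_like | budgie_like | nonlearner |
|---|---|---|---|
| w_pitch, w_amp | 1.0, 0.9 | 0.18, 0.22 | 0, 0 |
| w_dur, w_vowel | 0.0, 0.0 | 0.16, 0.22 | 0, 0 |
| σ | 0.25 | 0.33 | 0.3 |
| lapse / bias | 0.02 / 0.5 | 0.04 / 0.45 | 0.05 / 0.5 |
| λ (learn rate) | 0.3 | 0.003 | 0.3 |
| ceiling | 0.98 | 0.95 | 0.98 |
| ν (novelty) | 0.2 | 1.3 | 0 |

`human_like` relies on pitch and amplitude: it passes every
one-cue-removed condition and pitch-only/amplitude-only, and is at
chance for duration-only and vowel-only.  `budgie_like` spreads weak
weights across all four cues with strong novelty sensitivity: it
passes duration-removed and pitch-removed but no single-cue condition.
Its small λ yields acquisition over tens of ~103-trial sessions
(typically ~50–100 sessions across preliminary + discrimination).
`nonlearner` detects sound onsets (so it passes preliminary training)
but carries no stress-cue information and is excluded at
discrimination.

## Statistics

* **DR** = %R(S+) / (%R(S+) + %R(S−)), cumulative or per session;
  undefined (flagged, not numeric) when the subject responded to
  nothing in the window.
* **Binomial tests** against p₀ = 0.5 report the uncorrected statistic
  z = (x − n/2)/√(n/4) — the form whose per-individual thresholds the
  design's reported values follow (e.g. z = 2.449 at 18/24, two-tailed
  p = 0.014) — together with the exact tail (authoritative for
  n < 30) and a continuity-corrected normal p.  The corrected normal
  agrees with the exact tail within 0.01 for n ≥ 30 across the full x
  grid; the uncorrected normal does not (it deviates by up to ~0.07
  near the null center), which is why both are retained.
* **Counting convention.** Published analyses of this design are
  ambiguous about whether n counts probe trials or probe go-responses.
  Both are computed (`basis="go_responses"` is the default;
  `"probe_trials"` scores withheld responses on S− probes as correct).
  Under pure guessing the go-responses basis is *conservative*: with a
  fixed number of probes per category, x given n is narrower than
  Binomial(n, ½), so its type-I error falls below the nominal α.  The
  probe-trials basis is exactly Binomial(24, ½) per individual and
  calibrates near α (true level 0.032 at α = 0.05 due to
  discreteness).  The test suite asserts both behaviors.
* **Pooling.** Species-level tests pool probe *trials* across subjects,
  each scored against its own subject's rewarded category
  (counterbalanced cohorts); per-subject rows are also reported, and a
  subject-mean alternative can be computed from them.

## Problem sizes and determinism

Simulated cohorts in the test suite use 20 subjects per species; a
human-like cohort runs in under a second, a budgerigar-like cohort in
a few seconds (each bird completes on the order of 10⁴ trials).  All
randomness flows from numpy `SeedSequence` spawning: one seed fully
determines schedules, observer noise and stimulus draws, and the
acceptance script derives independent named substreams from its single
`--seed`.

## Limitations

* The synthesizer produces stylized, fully controlled speech, not a
  recording of a human voice; findings about cue manipulations
  transfer, speaker-identity effects do not.  No perceptual-loudness
  (dB SPL) calibration is attempted.
* Observers are decision models, not cognitive claims; their presets
  reproduce the qualitative significance patterns, not per-subject
  numbers, and passing cohort tests therefore validates the pipeline's
  logic and statistics rather than any empirical claim about real
  humans or budgerigars.
* Subject-level results that depend on real participants (proportions
  of learners, pooled z magnitudes, per-condition percentages) are not
  reproduction targets; the pipeline reproduces the protocol's
  structure, the stimulus acoustics, and the analysis semantics.
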