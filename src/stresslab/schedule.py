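"""Go/no-go protocol: trial scheduling, reinforcement, phase criteria.

The protocol runs six phases in fixed order:

1. ``preliminary`` — single syllables; respond when a sound played
   (sound vs. no-sound trials, 5/5 per block of 10).
2. ``discrimination`` — two-syllable words; respond to the S+ stress
   pattern only (trochee/iamb 50/50 per block), reinforced 100 %.
3. ``pretest1`` — same, but S+ reinforced 85 % of the time (blurs the
   contrast with the unreinforced probes to come).
4. ``generalization`` — 120 trials; 20 % unreinforced probes drawn from
   the untrained word set, each of its 24 stimuli exactly once.
5. ``pretest2`` — brief return to pre-testing.
6. ``cue_test`` — 240 trials; 20 % unreinforced probes from a 48-stimulus
   cue-manipulation bank (3 exemplars x 8 manipulations x 2 patterns).

Progression criteria differ by species: humans use a phase-cumulative
discrimination ratio (DR >= 0.8 after at least 10 trials, with per-phase
trial maxima); budgerigars use session-level DRs (2 criterion sessions for
preliminary, 4 consecutive for discrimination, last 2 of >= 3 for
pre-testing, 1 for the second pre-test).  Subjects that hit a maximum
without reaching criterion are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lexicon import IAMBIC, TROCHAIC, StressPattern, WordSet
from .synthesis import (
    MANIPULATIONS,
    SyllableStimulus,
    WordStimulus,
    draw_cue_params,
    draw_word_parameters,
)

__all__ = [
    "SpeciesProfile",
    "HUMAN",
    "BUDGERIGAR",
    "TrialSpec",
    "TrialRecord",
    "FeedbackEvent",
    "PhaseOutcome",
    "PHASE_ORDER",
    "preliminary_pool",
    "make_preliminary_schedule",
    "make_discrimination_schedule",
    "make_generalization_schedule",
    "make_cue_probe_bank",
    "make_cue_test_schedule",
    "adjudicate_trial",
    "phase_controller",
    "draw_session_length",
]

PHASE_ORDER = (
    "preliminary",
    "discrimination",
    "pretest1",
    "generalization",
    "pretest2",
    "cue_test",
)

PRETEST_REINFORCE_PROB = 0.85
RESPONSE_WINDOW = 2.0  # s


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-species protocol parameters and progression criteria."""

    name: str
    sessioned: bool
    penalty_delay: float  # s lockout after responding to S-
    reward: str  # "points" | "food"
    criterion_dr: float = 0.8
    min_trials: int = 10  # minimum trials before a cumulative criterion
    # trial-count maxima (trial-criterion species, i.e. humans)
    prelim_max_trials: int = 100
    discrim_max_trials: int = 150
    pretest_max_trials: int = 50
    # session criteria (sessioned species, i.e. budgerigars)
    prelim_sessions_required: int = 2
    discrim_consecutive_sessions: int = 4
    pretest_min_sessions: int = 3
    pretest_final_sessions: int = 2
    second_pretest_sessions: int = 1
    session_trials_mean: float = 103.0
    session_trials_min: int = 40
    max_sessions: int = 150
    reward_points: int = 10
    penalty_points: int = -10


HUMAN = SpeciesProfile(name="human", sessioned=False, penalty_delay=5.0, reward="points")
BUDGERIGAR = SpeciesProfile(name="budgerigar", sessioned=True, penalty_delay=30.0, reward="food")


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: stimulus, role and reinforcement probability."""

    phase: str
    stimulus: WordStimulus | SyllableStimulus | None  # None on no-sound trials
    role: str  # Splus | Sminus | probe | sound | nosound
    reinforce_prob: float

    def __post_init__(self) -> None:
        if self.role == "probe" and self.reinforce_prob != 0.0:
            raise ValueError("probe trials are never reinforced")


@dataclass(frozen=True)
class FeedbackEvent:
    kind: str  # reward | penalty | none
    points: int = 0
    delay: float = 0.0


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    session: int
    phase: str
    role: str
    stimulus: dict
    responded: bool
    correct: bool
    feedback: str
    latency: float | None  # None when no response occurred


@dataclass(frozen=True)
class PhaseOutcome:
    phase: str
    trials_used: int
    sessions_used: int
    passed: bool
    final_dr: float | None


def describe_stimulus(stim: WordStimulus | SyllableStimulus | None) -> dict:
    """Compact JSON-friendly stimulus descriptor for trial logs."""
    if stim is None:
        return {"kind": "silence"}
    if isinstance(stim, SyllableStimulus):
        return {
            "kind": "syllable",
            "syllable": stim.syllable.text,
            "stressed": stim.stressed,
        }
    return {
        "kind": "word",
        "word": stim.word.text,
        "pattern": stim.pattern,
        "manipulation": stim.manipulation,
    }


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


def _interleave_block(rng: np.random.Generator, *groups: Sequence[TrialSpec]) -> list[TrialSpec]:
    block = [t for g in groups for t in g]
    order = rng.permutation(len(block))
    return [block[i] for i in order]


def preliminary_pool(word_set: WordSet, rng: np.random.Generator) -> list[SyllableStimulus]:
    """Stressed and unstressed tokens of each training-set syllable
    (6 syllables x 2 stress states = 12 stimuli, parameters drawn once)."""
    pool = []
    for syll in word_set.syllables:
        for stressed in (True, False):
            pool.append(SyllableStimulus(syll, stressed, draw_cue_params(stressed, rng)))
    return pool


def make_preliminary_schedule(
    pool: Sequence[SyllableStimulus],
    rng: np.random.Generator,
    n_trials: int = 100,
    phase: str = "preliminary",
) -> list[TrialSpec]:
    """Sound/no-sound trials in blocks of 10 (5 sound, 5 silence).

    Sound trials cycle through the pool in random order without
    replacement, reshuffling once exhausted.
    """
    if not pool:
        raise ValueError("empty syllable pool")
    cycle: list[SyllableStimulus] = []

    def next_sound() -> SyllableStimulus:
        nonlocal cycle
        if not cycle:
            cycle = [pool[i] for i in rng.permutation(len(pool))]
        return cycle.pop()

    trials: list[TrialSpec] = []
    n_blocks = -(-n_trials // 10)
    for _ in range(n_blocks):
        # randomize sound/no-sound positions but keep the syllable cycle's
        # presentation order, so "without replacement" holds as heard
        is_sound = rng.permutation(10) < 5
        for sound in is_sound:
            if sound:
                trials.append(TrialSpec(phase, next_sound(), "sound", 1.0))
            else:
                trials.append(TrialSpec(phase, None, "nosound", 0.0))
    return trials[:n_trials]


def make_discrimination_schedule(
    word_set: WordSet,
    splus_pattern: StressPattern,
    rng: np.random.Generator,
    n_trials: int = 150,
    reinforce_prob: float = 1.0,
    phase: str = "discrimination",
) -> list[TrialSpec]:
    """Two-syllable word trials, 5 trochees / 5 iambs per block of 10.

    Roles follow ``splus_pattern``; the pre-testing variant is obtained
    with ``reinforce_prob=0.85``.
    """
    if splus_pattern not in (TROCHAIC, IAMBIC):
        raise ValueError(f"unknown S+ pattern {splus_pattern!r}")
    sminus_pattern = IAMBIC if splus_pattern == TROCHAIC else TROCHAIC
    words = word_set.words
    trials: list[TrialSpec] = []
    n_blocks = -(-n_trials // 10)
    for _ in range(n_blocks):
        splus = [
            TrialSpec(
                phase,
                draw_word_parameters(words[int(i)], splus_pattern, "none", rng),
                "Splus",
                reinforce_prob,
            )
            for i in rng.choice(len(words), 5)
        ]
        sminus = [
            TrialSpec(
                phase,
                draw_word_parameters(words[int(i)], sminus_pattern, "none", rng),
                "Sminus",
                0.0,
            )
            for i in rng.choice(len(words), 5)
        ]
        trials.extend(_interleave_block(rng, splus, sminus))
    return trials[:n_trials]


def _training_blocks(
    word_set: WordSet,
    splus_pattern: StressPattern,
    rng: np.random.Generator,
    n_blocks: int,
    repeats: int,
    phase: str,
) -> tuple[list[list[TrialSpec]], list[list[TrialSpec]]]:
    """Shuffle ``repeats`` copies of each trained stimulus into blocks of 4."""
    sminus_pattern = IAMBIC if splus_pattern == TROCHAIC else TROCHAIC
    out = []
    for pattern, role, prob in (
        (splus_pattern, "Splus", PRETEST_REINFORCE_PROB),
        (sminus_pattern, "Sminus", 0.0),
    ):
        specs = [
            TrialSpec(phase, draw_word_parameters(w, pattern, "none", rng), role, prob)
            for w in word_set.words
            for _ in range(repeats)
        ]
        order = rng.permutation(len(specs))
        specs = [specs[i] for i in order]
        assert len(specs) == 4 * n_blocks
        out.append([specs[4 * b : 4 * b + 4] for b in range(n_blocks)])
    return out[0], out[1]


def make_generalization_schedule(
    trained_set: WordSet,
    probe_set: WordSet,
    splus_pattern: StressPattern,
    rng: np.random.Generator,
) -> list[TrialSpec]:
    """Novel-word test: 120 trials in 12 blocks of 10.

    Each block holds 2 unreinforced probes (untrained words) + 4 trained
    S+ + 4 trained S-.  Each of the 24 probe stimuli (12 words x 2
    patterns) occurs exactly once; each trained stimulus exactly 4 times.
    Trained S+ remain reinforced at the 85 % pre-testing rate.
    """
    if set(trained_set.syllables) & set(probe_set.syllables):
        raise ValueError("trained and probe word sets must be disjoint")
    phase = "generalization"
    probes = [
        TrialSpec(phase, draw_word_parameters(w, pattern, "none", rng), "probe", 0.0)
        for w in probe_set.words
        for pattern in (TROCHAIC, IAMBIC)
    ]
    order = rng.permutation(len(probes))
    probes = [probes[i] for i in order]
    splus_blocks, sminus_blocks = _training_blocks(
        trained_set, splus_pattern, rng, n_blocks=12, repeats=4, phase=phase
    )
    trials: list[TrialSpec] = []
    for b in range(12):
        trials.extend(
            _interleave_block(rng, probes[2 * b : 2 * b + 2], splus_blocks[b], sminus_blocks[b])
        )
    return trials


def make_cue_probe_bank(
    word_set: WordSet, rng: np.random.Generator, exemplars: int = 3
) -> list[WordStimulus]:
    """The 48-stimulus cue-test probe bank: ``exemplars`` random word
    exemplars for each of the 8 manipulations for each stress pattern."""
    bank = []
    for manipulation in MANIPULATIONS:
        if manipulation == "none":
            continue
        for pattern in (TROCHAIC, IAMBIC):
            idx = rng.choice(len(word_set.words), size=exemplars, replace=False)
            for i in idx:
                bank.append(
                    draw_word_parameters(word_set.words[int(i)], pattern, manipulation, rng)
                )
    return bank


def make_cue_test_schedule(
    trained_set: WordSet,
    probe_bank: Sequence[WordStimulus],
    splus_pattern: StressPattern,
    rng: np.random.Generator,
) -> list[TrialSpec]:
    """Absent-cue test: 240 trials in 24 blocks of 10.

    2 unreinforced probes per block, each of the 48 bank stimuli exactly
    once; 4 trained S+ and 4 trained S- per block (each trained stimulus
    8 times in all).
    """
    if len(probe_bank) != 48:
        raise ValueError(f"cue-test probe bank must hold 48 stimuli, got {len(probe_bank)}")
    phase = "cue_test"
    probes = [TrialSpec(phase, stim, "probe", 0.0) for stim in probe_bank]
    order = rng.permutation(len(probes))
    probes = [probes[i] for i in order]
    splus_blocks, sminus_blocks = _training_blocks(
        trained_set, splus_pattern, rng, n_blocks=24, repeats=8, phase=phase
    )
    trials: list[TrialSpec] = []
    for b in range(24):
        trials.extend(
            _interleave_block(rng, probes[2 * b : 2 * b + 2], splus_blocks[b], sminus_blocks[b])
        )
    return trials


# ---------------------------------------------------------------------------
# reinforcement
# ---------------------------------------------------------------------------


def adjudicate_trial(
    spec: TrialSpec,
    responded: bool,
    rng: np.random.Generator,
    profile: SpeciesProfile = HUMAN,
) -> FeedbackEvent:
    """Apply the reinforcement contingency to one trial.

    Responding to S+ (or a preliminary sound trial) earns reward with
    probability ``spec.reinforce_prob``; responding to S- (or silence)
    earns the species penalty; probes and withheld responses produce no
    feedback.
    """
    if not responded or spec.role == "probe":
        return FeedbackEvent("none")
    if spec.role in ("Splus", "sound"):
        if rng.random() < spec.reinforce_prob:
            points = profile.reward_points if profile.reward == "points" else 0
            return FeedbackEvent("reward", points=points)
        return FeedbackEvent("none")
    if spec.role in ("Sminus", "nosound"):
        points = profile.penalty_points if profile.reward == "points" else 0
        return FeedbackEvent("penalty", points=points, delay=profile.penalty_delay)
    raise ValueError(f"unknown trial role {spec.role!r}")


def draw_session_length(profile: SpeciesProfile, rng: np.random.Generator) -> int:
    """Trials in one sessioned-species session: Poisson around the mean,
    truncated below at the minimum."""
    return max(int(rng.poisson(profile.session_trials_mean)), profile.session_trials_min)


# ---------------------------------------------------------------------------
# phase progression
# ---------------------------------------------------------------------------

_TRIAL_MAXIMA = {
    "preliminary": "prelim_max_trials",
    "discrimination": "discrim_max_trials",
    "pretest1": "pretest_max_trials",
    "pretest2": "pretest_max_trials",
}


def phase_controller(
    profile: SpeciesProfile,
    phase: str,
    cumulative_dr: float | None,
    trials_used: int,
    session_drs: Sequence[float] | None = None,
) -> str:
    """Decide ``"advance"``, ``"continue"`` or ``"fail"`` for the current
    phase given the history so far.

    For trial-criterion species, ``cumulative_dr`` is the phase-cumulative
    DR after ``trials_used`` trials.  For sessioned species,
    ``session_drs`` lists the DR of each completed session of the phase
    (the call is made at session boundaries).
    """
    if phase in ("generalization", "cue_test"):
        # fixed-length tests: the runner advances when all trials are done
        return "advance"
    if phase not in _TRIAL_MAXIMA:
        raise ValueError(f"unknown phase {phase!r}")

    if not profile.sessioned:
        max_trials = getattr(profile, _TRIAL_MAXIMA[phase])
        if (
            trials_used >= profile.min_trials
            and cumulative_dr is not None
            and cumulative_dr >= profile.criterion_dr
        ):
            return "advance"
        return "fail" if trials_used >= max_trials else "continue"

    drs = list(session_drs or [])
    crit = [dr is not None and dr >= profile.criterion_dr for dr in drs]
    if phase == "preliminary":
        done = sum(crit) >= profile.prelim_sessions_required
    elif phase == "discrimination":
        k = profile.discrim_consecutive_sessions
        done = len(crit) >= k and all(crit[-k:])
    elif phase == "pretest1":
        k = profile.pretest_final_sessions
        done = len(crit) >= profile.pretest_min_sessions and all(crit[-k:])
    else:  # pretest2
        k = profile.second_pretest_sessions
        done = len(crit) >= k and all(crit[-k:])
    if done:
        return "advance"
    return "fail" if len(drs) >= profile.max_sessions else "continue"
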