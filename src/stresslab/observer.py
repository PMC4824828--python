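"""Simulated go/no-go subjects (the synthetic-data generator).

Each observer perceives a word stimulus through a weighted sum of four
normalized stress cues (pitch excursion, relative level, duration, vowel
fullness) per syllable, plus Gaussian decision noise; the syllable with
the higher stress salience determines the perceived pattern (trochaic or
iambic).  Responding is governed by a learned percept -> go association
updated by a delta rule after rewards and penalties; probes and withheld
responses never update it.  A lapse term mixes in baseline guessing, and
a novelty term shrinks responding toward baseline on stimuli whose cue
configuration departs from anything heard in training (probes with
neutralized cues), which is what lets a "budgie-like" observer retain
discrimination when one cue is removed yet fall to chance when three are.

The cue weights of the two shipped species presets encode the study's
qualitative signatures, not fitted subject data: the human-like preset
leans on pitch and amplitude (duration or vowel quality alone are not
usable), the budgie-like preset spreads weak weights over all four cues
and is strongly novelty-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lexicon import IAMBIC, TROCHAIC, StressPattern, build_training_sets
from .schedule import (
    PHASE_ORDER,
    PRETEST_REINFORCE_PROB,
    PhaseOutcome,
    SpeciesProfile,
    TrialRecord,
    TrialSpec,
    adjudicate_trial,
    describe_stimulus,
    draw_session_length,
    make_cue_probe_bank,
    make_cue_test_schedule,
    make_discrimination_schedule,
    make_generalization_schedule,
    make_preliminary_schedule,
    phase_controller,
    preliminary_pool,
)
from .synthesis import (
    F0_BASE,
    STRESSED_RMS,
    WordStimulus,
    estimate_f0,
    measure_rms,
    removed_cues,
)

__all__ = [
    "ObserverProfile",
    "ObserverState",
    "PerceptDescriptor",
    "Percept",
    "PRESETS",
    "perceive",
    "respond",
    "update",
    "simulate_subject",
    "simulate_cohort",
    "assign_counterbalance",
    "SubjectResult",
]

#: Pitch normalization: maximal stressed excursion in semitones
#: (12 * log2(280/194)), so a peak at 280 Hz maps to 1.
MAX_PITCH_EXCURSION_ST = 12.0 * np.log2(280.0 / F0_BASE)


@dataclass(frozen=True)
class ObserverProfile:
    """Decision-model parameters of one simulated subject."""

    name: str
    w_pitch: float
    w_amp: float
    w_dur: float
    w_vowel: float
    sigma: float  # decision-noise SD on each syllable's salience
    lapse: float  # probability of baseline (unlearned) responding
    go_bias: float  # baseline go probability
    learn_rate: float
    response_prob_ceiling: float = 0.98
    novelty_sensitivity: float = 0.0  # reversion toward baseline on atypical stimuli
    sound_detect_accuracy: float = 0.98  # preliminary-phase sound detection

    def __post_init__(self) -> None:
        if min(self.w_pitch, self.w_amp, self.w_dur, self.w_vowel) < 0:
            raise ValueError("cue weights must be nonnegative")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        for name in ("lapse", "go_bias", "learn_rate", "response_prob_ceiling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w_pitch, self.w_amp, self.w_dur, self.w_vowel])


#: Species presets.  Parameters are chosen to reproduce the qualitative
#: species signatures (acquisition within the protocol's limits; the
#: pattern of significant/at-chance cue-removal conditions), not fitted
#: to any subject's data.
PRESETS: dict[str, ObserverProfile] = {
    "human_like": ObserverProfile(
        name="human_like",
        w_pitch=1.0,
        w_amp=0.9,
        w_dur=0.0,
        w_vowel=0.0,
        sigma=0.25,
        lapse=0.02,
        go_bias=0.5,
        learn_rate=0.3,
        response_prob_ceiling=0.98,
        novelty_sensitivity=0.2,
    ),
    "budgie_like": ObserverProfile(
        name="budgie_like",
        w_pitch=0.18,
        w_amp=0.22,
        w_dur=0.16,
        w_vowel=0.22,
        sigma=0.33,
        lapse=0.04,
        go_bias=0.45,
        learn_rate=0.003,
        response_prob_ceiling=0.95,
        novelty_sensitivity=1.3,
    ),
    "nonlearner": ObserverProfile(
        name="nonlearner",
        w_pitch=0.0,
        w_amp=0.0,
        w_dur=0.0,
        w_vowel=0.0,
        sigma=0.3,
        lapse=0.05,
        go_bias=0.5,
        learn_rate=0.3,
    ),
}


@dataclass
class ObserverState:
    """Learned percept -> go association strengths, all bounded to [0, 1]."""

    associations: dict[str, float]
    trial_count: int = 0

    @classmethod
    def initial(cls, profile: ObserverProfile) -> "ObserverState":
        a0 = profile.go_bias
        return cls(
            associations={TROCHAIC: a0, IAMBIC: a0, "sound": a0, "nosound": a0}
        )


@dataclass(frozen=True)
class PerceptDescriptor:
    """Normalized cue evidence per syllable, shape (2 syllables, 4 cues).

    Cue order: pitch, amplitude, duration, vowel; all roughly on [0, 1]
    with 1 at the stressed target.  Derived from stimulus parameters (not
    audio) so that protocol simulation is fast; the audio-derived path
    must agree within measurement tolerance.
    """

    cues: np.ndarray
    n_neutralized: int = 0

    @property
    def atypicality(self) -> float:
        """Fraction of cues neutralized relative to training stimuli."""
        return self.n_neutralized / 4.0

    @staticmethod
    def _normalize(f0_peak: float, rms: float, duration: float, vowel_mode: str) -> list[float]:
        pitch = 12.0 * np.log2(max(f0_peak, 1e-6) / F0_BASE) / MAX_PITCH_EXCURSION_ST
        amp_db = 20.0 * np.log10(max(rms, 1e-9) / STRESSED_RMS)
        amp = float(np.clip(1.0 + amp_db / 10.0, 0.0, 1.0))
        dur = float(np.clip((duration - 0.3) / 0.2, 0.0, 1.0))
        vowel = 1.0 if vowel_mode == "full" else 0.0
        return [float(np.clip(pitch, 0.0, 1.0)), amp, dur, vowel]

    @classmethod
    def from_stimulus(cls, stim: WordStimulus) -> "PerceptDescriptor":
        rows = [
            cls._normalize(p.f0_peak, p.rms_target, p.duration, p.vowel_mode)
            for p in stim.syllable_params
        ]
        return cls(np.array(rows), n_neutralized=len(removed_cues(stim.manipulation)))

    @classmethod
    def from_audio(cls, stim: WordStimulus) -> "PerceptDescriptor":
        """Slow audio-measurement path (QC): per-syllable RMS, duration and
        terminal f0 measured from the waveform; vowel mode from metadata
        (vowel identity is a spectral property not re-estimated here)."""
        if stim.audio is None:
            raise ValueError("stimulus carries no audio")
        fs = stim.audio.sample_rate
        n1 = int(round(stim.syllable_params[0].duration * fs))
        segments = [stim.audio.samples[:n1], stim.audio.samples[n1:]]
        rows = []
        for seg, params in zip(segments, stim.syllable_params):
            from .synthesis import Waveform

            w = Waveform(seg, fs)
            track = estimate_f0(w)
            voiced = track.voiced_values
            f0_end = float(voiced[-1]) if voiced.size else F0_BASE
            rows.append(
                cls._normalize(f0_end, measure_rms(w), w.duration, params.vowel_mode)
            )
        return cls(np.array(rows), n_neutralized=len(removed_cues(stim.manipulation)))


@dataclass(frozen=True)
class Percept:
    pattern: StressPattern
    ambiguous: bool
    salience_diff: float


_AMBIGUITY_FLOOR = 1e-12


def perceive(
    descriptor: PerceptDescriptor,
    profile: ObserverProfile,
    rng: np.random.Generator,
) -> Percept:
    """Infer the stress pattern from weighted cue evidence plus noise.

    Salience per syllable is the weighted cue sum plus independent
    Gaussian noise; the higher-salience slot wins.  When the difference
    sits below the ambiguity floor (only possible in near-noiseless,
    cue-free configurations) a fair coin decides.
    """
    salience = descriptor.cues @ profile.weights
    if profile.sigma > 0:
        salience = salience + rng.normal(0.0, profile.sigma, size=2)
    diff = float(salience[0] - salience[1])
    if abs(diff) <= _AMBIGUITY_FLOOR:
        return Percept(TROCHAIC if rng.random() < 0.5 else IAMBIC, True, diff)
    return Percept(TROCHAIC if diff > 0 else IAMBIC, False, diff)


def respond(
    percept_category: str,
    state: ObserverState,
    profile: ObserverProfile,
    rng: np.random.Generator,
    atypicality: float = 0.0,
) -> bool:
    """Draw a go/no-go response.

    Go probability mixes the learned association with baseline guessing
    through the lapse rate, shrinks toward baseline in proportion to
    stimulus atypicality (novelty), and is capped by the response
    ceiling.
    """
    assoc = state.associations[percept_category]
    reversion = float(np.clip(profile.novelty_sensitivity * atypicality, 0.0, 1.0))
    assoc_eff = (1.0 - reversion) * assoc + reversion * profile.go_bias
    p_go = profile.lapse * profile.go_bias + (1.0 - profile.lapse) * assoc_eff
    p_go = min(p_go, profile.response_prob_ceiling)
    return bool(rng.random() < p_go)


def update(
    state: ObserverState,
    percept_category: str,
    feedback_kind: str,
    profile: ObserverProfile,
) -> ObserverState:
    """Delta-rule association update; no-feedback trials leave the state
    unchanged.  Associations stay in [0, 1] by construction."""
    state.trial_count += 1
    if feedback_kind == "reward":
        target = 1.0
    elif feedback_kind == "penalty":
        target = 0.0
    else:
        return state
    a = state.associations[percept_category]
    state.associations[percept_category] = a + profile.learn_rate * (target - a)
    return state


# ---------------------------------------------------------------------------
# protocol driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectResult:
    subject_id: str
    observer: str
    species: str
    trained_set_id: int
    splus_pattern: StressPattern
    seed: int
    records: list[TrialRecord]
    outcomes: list[PhaseOutcome]
    completed: bool

    @property
    def excluded(self) -> bool:
        return not self.completed


def assign_counterbalance(subject_index: int) -> tuple[int, StressPattern]:
    """Deterministic training-set x S+-pattern assignment by subject index."""
    set_id = 1 + subject_index % 2
    pattern = TROCHAIC if (subject_index // 2) % 2 == 0 else IAMBIC
    return set_id, pattern


def _run_trial(
    spec: TrialSpec,
    state: ObserverState,
    observer: ObserverProfile,
    species: SpeciesProfile,
    rng: np.random.Generator,
    trial_index: int,
    session_index: int,
) -> TrialRecord:
    if spec.role in ("sound", "nosound"):
        truth = "sound" if spec.role == "sound" else "nosound"
        if rng.random() < observer.sound_detect_accuracy:
            percept = truth
        else:
            percept = "nosound" if truth == "sound" else "sound"
        atypicality = 0.0
    else:
        descriptor = PerceptDescriptor.from_stimulus(spec.stimulus)
        percept = perceive(descriptor, observer, rng).pattern
        atypicality = descriptor.atypicality
    go = respond(percept, state, observer, rng, atypicality=atypicality)
    feedback = adjudicate_trial(spec, go, rng, species)
    update(state, percept, feedback.kind, observer)
    if spec.role == "probe":
        # scored against the probe's own stress category by the analysis;
        # recorded here as "did the subject respond at all"
        correct = go
    else:
        correct = go == (spec.role in ("Splus", "sound"))
    latency = float(min(0.3 + rng.exponential(0.35), 2.0)) if go else None
    return TrialRecord(
        trial=trial_index,
        session=session_index,
        phase=spec.phase,
        role=spec.role,
        stimulus=describe_stimulus(spec.stimulus),
        responded=go,
        correct=bool(correct),
        feedback=feedback.kind,
        latency=latency,
    )


def _cumulative_dr(n_sp, r_sp, n_sm, r_sm) -> float | None:
    if n_sp == 0 or n_sm == 0:
        return None
    p_sp = r_sp / n_sp
    p_sm = r_sm / n_sm
    if p_sp + p_sm == 0:
        return None
    return p_sp / (p_sp + p_sm)


class _PhaseRunner:
    """Runs one phase for one subject, tracking DRs and the controller."""

    def __init__(self, subject, phase: str):
        self.s = subject
        self.phase = phase
        self.n_sp = self.r_sp = self.n_sm = self.r_sm = 0
        self.sess_counts = [0, 0, 0, 0]  # n_sp, r_sp, n_sm, r_sm this session
        self.session_drs: list[float | None] = []
        self.trials_used = 0
        self.sessions_used = 0

    def run_trial(self, spec: TrialSpec) -> TrialRecord:
        s = self.s
        rec = _run_trial(
            spec, s.state, s.observer, s.species, s.rng_obs, s.trial_counter, s.session_counter
        )
        s.records.append(rec)
        s.trial_counter += 1
        self.trials_used += 1
        if rec.role in ("Splus", "sound"):
            self.n_sp += 1
            self.r_sp += rec.responded
            self.sess_counts[0] += 1
            self.sess_counts[1] += rec.responded
        elif rec.role in ("Sminus", "nosound"):
            self.n_sm += 1
            self.r_sm += rec.responded
            self.sess_counts[2] += 1
            self.sess_counts[3] += rec.responded
        return rec

    def end_session(self) -> None:
        n_sp, r_sp, n_sm, r_sm = self.sess_counts
        self.session_drs.append(_cumulative_dr(n_sp, r_sp, n_sm, r_sm))
        self.sess_counts = [0, 0, 0, 0]
        self.sessions_used += 1
        self.s.session_counter += 1

    @property
    def cumulative_dr(self) -> float | None:
        return _cumulative_dr(self.n_sp, self.r_sp, self.n_sm, self.r_sm)

    def outcome(self, passed: bool) -> PhaseOutcome:
        return PhaseOutcome(
            self.phase,
            self.trials_used,
            self.sessions_used,
            passed,
            self.cumulative_dr,
        )


class _Subject:
    def __init__(self, observer, species, seed):
        self.observer = observer
        self.species = species
        ss = np.random.SeedSequence(seed)
        sched_ss, obs_ss = ss.spawn(2)
        self.rng_sched = np.random.default_rng(sched_ss)
        self.rng_obs = np.random.default_rng(obs_ss)
        self.state = ObserverState.initial(observer)
        self.records: list[TrialRecord] = []
        self.trial_counter = 0
        self.session_counter = 0


def _run_criterion_phase(subject: _Subject, phase: str, make_chunk) -> PhaseOutcome:
    """A phase governed by a DR criterion.

    ``make_chunk(n)`` yields n scheduled trials.  Humans are evaluated
    after every trial against the phase-cumulative DR; budgerigars at
    session boundaries against session DRs.
    """
    runner = _PhaseRunner(subject, phase)
    species = subject.species
    if not species.sessioned:
        max_trials = {
            "preliminary": species.prelim_max_trials,
            "discrimination": species.discrim_max_trials,
            "pretest1": species.pretest_max_trials,
            "pretest2": species.pretest_max_trials,
        }[phase]
        for spec in make_chunk(max_trials):
            runner.run_trial(spec)
            decision = phase_controller(
                species, phase, runner.cumulative_dr, runner.trials_used
            )
            if decision != "continue":
                break
        runner.end_session()
        return runner.outcome(decision == "advance")
    while True:
        n = draw_session_length(species, subject.rng_sched)
        for spec in make_chunk(n):
            runner.run_trial(spec)
        runner.end_session()
        decision = phase_controller(
            species, phase, runner.cumulative_dr, runner.trials_used,
            session_drs=runner.session_drs,
        )
        if decision != "continue":
            return runner.outcome(decision == "advance")


def _run_fixed_phase(subject: _Subject, phase: str, trials: Sequence[TrialSpec]) -> PhaseOutcome:
    """A fixed-length test phase.  Sessioned species may split it across
    sessions (resumable cursor); the phase always completes."""
    runner = _PhaseRunner(subject, phase)
    species = subject.species
    cursor = 0
    while cursor < len(trials):
        n = (
            draw_session_length(species, subject.rng_sched)
            if species.sessioned
            else len(trials)
        )
        for spec in trials[cursor : cursor + n]:
            runner.run_trial(spec)
        cursor += n
        runner.end_session()
    return runner.outcome(True)


def simulate_subject(
    observer: ObserverProfile,
    species: SpeciesProfile,
    seed: int,
    trained_set_id: int = 1,
    splus_pattern: StressPattern = TROCHAIC,
    subject_id: str = "subject0",
) -> SubjectResult:
    """Run one subject through the complete six-phase protocol.

    Deterministic under a fixed seed.  A subject that fails a criterion
    phase is excluded: later phases are not run and ``completed`` is
    False.
    """
    set1, set2 = build_training_sets()
    trained = set1 if trained_set_id == 1 else set2
    probe_set = set2 if trained_set_id == 1 else set1
    subject = _Subject(observer, species, seed)
    rng = subject.rng_sched

    pool = preliminary_pool(trained, rng)
    outcomes: list[PhaseOutcome] = []

    def finish(completed: bool) -> SubjectResult:
        return SubjectResult(
            subject_id,
            observer.name,
            species.name,
            trained_set_id,
            splus_pattern,
            seed,
            subject.records,
            outcomes,
            completed,
        )

    phase_makers = {
        "preliminary": lambda n: make_preliminary_schedule(pool, rng, n),
        "discrimination": lambda n: make_discrimination_schedule(
            trained, splus_pattern, rng, n, reinforce_prob=1.0, phase="discrimination"
        ),
        "pretest1": lambda n: make_discrimination_schedule(
            trained, splus_pattern, rng, n,
            reinforce_prob=PRETEST_REINFORCE_PROB, phase="pretest1",
        ),
        "pretest2": lambda n: make_discrimination_schedule(
            trained, splus_pattern, rng, n,
            reinforce_prob=PRETEST_REINFORCE_PROB, phase="pretest2",
        ),
    }
    for phase in PHASE_ORDER:
        if phase in phase_makers:
            outcome = _run_criterion_phase(subject, phase, phase_makers[phase])
        elif phase == "generalization":
            trials = make_generalization_schedule(trained, probe_set, splus_pattern, rng)
            outcome = _run_fixed_phase(subject, phase, trials)
        else:  # cue_test
            bank = make_cue_probe_bank(trained, rng)
            trials = make_cue_test_schedule(trained, bank, splus_pattern, rng)
            outcome = _run_fixed_phase(subject, phase, trials)
        outcomes.append(outcome)
        if not outcome.passed:
            return finish(False)
    return finish(True)


def simulate_cohort(
    observer: ObserverProfile,
    species: SpeciesProfile,
    n_subjects: int,
    seed: int,
) -> list[SubjectResult]:
    """Simulate a counterbalanced cohort; subject seeds derive from the
    cohort seed, so the whole cohort is reproducible."""
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    results = []
    for i, child in enumerate(children):
        set_id, pattern = assign_counterbalance(i)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        results.append(
            simulate_subject(
                observer, species, sub_seed, set_id, pattern, subject_id=f"subject{i}"
            )
        )
    return results
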