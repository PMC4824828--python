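"""Response measures and statistics for go/no-go trial logs.

The central response measure is the discrimination ratio

    DR = %response(S+) / (%response(S+) + %response(S-))

where 0.5 means equal responding to both classes and 1.0 perfect
discrimination.  Generalization is assessed with binomial tests on probe
responses against the chance null p0 = 0.5, using the z statistic
z = (x - n/2) / sqrt(n/4) with no continuity correction (this is the form
whose per-individual thresholds the study's reported values follow, e.g.
z = 2.449 at x = 18 of n = 24).  Because per-individual probe counts are
small, the exact binomial tail is computed alongside and is authoritative
for n < 30; a continuity-corrected normal p is also reported, which
tracks the exact tail within 0.01 for n >= 30.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .lexicon import StressPattern
from .synthesis import MANIPULATIONS
from .schedule import PHASE_ORDER, PhaseOutcome, SpeciesProfile, TrialRecord, phase_controller

__all__ = [
    "DRResult",
    "BinomialResult",
    "CueTestSummary",
    "GeneralizationReport",
    "CriterionTrace",
    "discrimination_ratio",
    "category_binomial",
    "generalization_report",
    "cue_test_report",
    "criterion_trace",
]

_SPLUS_ROLES = ("Splus", "sound")
_SMINUS_ROLES = ("Sminus", "nosound")

#: Below this count the exact binomial tail is authoritative.
EXACT_TEST_MAX_N = 30


@dataclass(frozen=True)
class DRResult:
    """Discrimination ratio over one window of S+/S- trials."""

    percent_splus: float
    percent_sminus: float
    dr: float | None  # None = undefined (no responding at all)
    n_splus: int
    n_sminus: int

    @property
    def undefined(self) -> bool:
        return self.dr is None


def discrimination_ratio(records: Sequence) -> DRResult:
    """DR over a window of trial records (probe trials are ignored).

    The window must contain at least one S+ and one S- trial.  When the
    subject responded to nothing, the ratio is undefined and flagged
    rather than returned as a number.
    """
    n_sp = n_sm = r_sp = r_sm = 0
    for rec in records:
        if rec.role in _SPLUS_ROLES:
            n_sp += 1
            r_sp += bool(rec.responded)
        elif rec.role in _SMINUS_ROLES:
            n_sm += 1
            r_sm += bool(rec.responded)
    if n_sp == 0 or n_sm == 0:
        raise ValueError("DR window needs at least one S+ and one S- trial")
    pct_sp = 100.0 * r_sp / n_sp
    pct_sm = 100.0 * r_sm / n_sm
    denom = pct_sp + pct_sm
    dr = pct_sp / denom if denom > 0 else None
    return DRResult(pct_sp, pct_sm, dr, n_sp, n_sm)


@dataclass(frozen=True)
class BinomialResult:
    """Binomial test of x successes in n against p0 = 0.5.

    ``z`` is the uncorrected normal statistic (x - n/2)/sqrt(n/4).  ``p``
    is the authoritative p-value: the exact tail for n < 30, otherwise
    the normal approximation.  All variants are retained for inspection.
    """

    x: int
    n: int
    tail: str  # "one" | "two"
    z: float
    p: float
    p_exact: float
    p_normal: float
    p_normal_corrected: float
    basis: str = "go_responses"

    @property
    def undefined(self) -> bool:
        return self.n == 0


def _binomial_result(x: int, n: int, tail: str, basis: str) -> BinomialResult:
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if n == 0:
        nan = float("nan")
        return BinomialResult(0, 0, tail, nan, nan, nan, nan, nan, basis)
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    s = np.sqrt(n / 4.0)
    z = (x - n / 2.0) / s
    if tail == "one":
        p_exact = stats.binomtest(x, n, 0.5, alternative="greater").pvalue
        p_normal = stats.norm.sf(z)
        p_corr = stats.norm.sf((x - 0.5 - n / 2.0) / s)
    else:
        p_exact = stats.binomtest(x, n, 0.5, alternative="two-sided").pvalue
        p_normal = 2.0 * stats.norm.sf(abs(z))
        p_corr = 2.0 * stats.norm.sf((abs(x - n / 2.0) - 0.5) / s)
    p_corr = float(min(p_corr, 1.0))
    p = float(p_exact) if n < EXACT_TEST_MAX_N else float(p_normal)
    return BinomialResult(x, n, tail, float(z), p, float(p_exact), float(p_normal), p_corr, basis)


def _probe_pattern(rec: TrialRecord) -> StressPattern:
    return rec.stimulus["pattern"]


def _category_counts(
    probes: Sequence[TrialRecord],
    splus_patterns: Sequence[StressPattern],
    basis: str,
) -> tuple[int, int]:
    """(x, n) for category tests; each probe is scored against its own
    subject's rewarded pattern (cohorts are counterbalanced)."""
    if basis == "go_responses":
        x = n = 0
        for rec, pattern in zip(probes, splus_patterns):
            if rec.responded:
                n += 1
                x += _probe_pattern(rec) == pattern
        return x, n
    if basis == "probe_trials":
        x = sum(
            rec.responded == (_probe_pattern(rec) == pattern)
            for rec, pattern in zip(probes, splus_patterns)
        )
        return x, len(probes)
    raise ValueError(f"unknown basis {basis!r}")


def category_binomial(
    probe_records: Sequence[TrialRecord],
    splus_pattern: StressPattern | Sequence[StressPattern],
    tail: str = "one",
    basis: str = "go_responses",
) -> BinomialResult:
    """Test whether probe responding favors the trained rewarded category.

    With the default ``go_responses`` basis, x counts go-responses to
    probes of the rewarded stress pattern and n all go-responses to
    probes.  The ``probe_trials`` basis instead counts every probe trial,
    scoring a trial correct when the response matches its category (go on
    rewarded-pattern probes, no-go on unrewarded-pattern probes); both
    conventions are reported because the counted n is ambiguous in
    published analyses of this design.

    ``splus_pattern`` may be a single pattern or one per record (needed
    when pooling counterbalanced subjects).
    """
    probes = [r for r in probe_records if r.role == "probe"]
    if isinstance(splus_pattern, str):
        patterns: Sequence[StressPattern] = [splus_pattern] * len(probes)
    else:
        patterns = [p for r, p in zip(probe_records, splus_pattern) if r.role == "probe"]
        if len(patterns) != len(probes):
            raise ValueError("one S+ pattern required per record")
    x, n = _category_counts(probes, patterns, basis)
    return _binomial_result(x, n, tail, basis)


@dataclass(frozen=True)
class GeneralizationReport:
    per_subject: pd.DataFrame
    pooled: BinomialResult
    pooled_two_tailed: BinomialResult


def _normalize_logs(
    logs: Mapping[str, Sequence[TrialRecord]] | Sequence[Sequence[TrialRecord]] | Sequence[TrialRecord],
) -> dict[str, list[TrialRecord]]:
    if isinstance(logs, Mapping):
        return {str(k): list(v) for k, v in logs.items()}
    logs = list(logs)
    if logs and isinstance(logs[0], TrialRecord):
        return {"subject0": logs}  # single subject
    return {f"subject{i}": list(v) for i, v in enumerate(logs)}


def _splus_pattern_of(records: Sequence[TrialRecord]) -> StressPattern:
    for rec in records:
        if rec.role == "Splus" and rec.stimulus.get("kind") == "word":
            return rec.stimulus["pattern"]
    raise ValueError("cannot infer S+ pattern: no word S+ trials in log")


def _percent_go(records: Sequence[TrialRecord]) -> float:
    return 100.0 * np.mean([r.responded for r in records]) if records else float("nan")


def generalization_report(
    logs,
    tail: str = "one",
) -> GeneralizationReport:
    """Novel-word test report: per-subject response percentages to the
    trained S+/S- and novel S+/S- categories with per-individual binomial
    tests, plus the trial-pooled test across subjects."""
    by_subject = _normalize_logs(logs)
    rows = []
    pooled_probes: list[TrialRecord] = []
    pooled_patterns: list[StressPattern] = []
    for subject, records in by_subject.items():
        phase_recs = [r for r in records if r.phase == "generalization"]
        if len(phase_recs) != 120:
            raise ValueError(
                f"subject {subject}: generalization phase incomplete "
                f"({len(phase_recs)}/120 trials)"
            )
        splus_pattern = _splus_pattern_of(phase_recs)
        probes = [r for r in phase_recs if r.role == "probe"]
        pooled_probes.extend(probes)
        pooled_patterns.extend([splus_pattern] * len(probes))
        novel_sp = [r for r in probes if _probe_pattern(r) == splus_pattern]
        novel_sm = [r for r in probes if _probe_pattern(r) != splus_pattern]
        trained_sp = [r for r in phase_recs if r.role == "Splus"]
        trained_sm = [r for r in phase_recs if r.role == "Sminus"]
        test = category_binomial(probes, splus_pattern, tail=tail)
        rows.append(
            {
                "subject": subject,
                "splus_pattern": splus_pattern,
                "trained_splus_pct": _percent_go(trained_sp),
                "trained_sminus_pct": _percent_go(trained_sm),
                "novel_splus_pct": _percent_go(novel_sp),
                "novel_sminus_pct": _percent_go(novel_sm),
                "x": test.x,
                "n": test.n,
                "z": test.z,
                "p": test.p,
                "undefined": test.undefined,
            }
        )
    pooled = category_binomial(pooled_probes, pooled_patterns, tail=tail)
    pooled_two = category_binomial(pooled_probes, pooled_patterns, tail="two")
    return GeneralizationReport(pd.DataFrame(rows), pooled, pooled_two)


@dataclass(frozen=True)
class CueTestSummary:
    """Per-manipulation pooled percent-correct and binomial tests."""

    table: pd.DataFrame
    results_one_tailed: dict[str, BinomialResult]
    results_two_tailed: dict[str, BinomialResult]


def cue_test_report(logs) -> CueTestSummary:
    """Absent-cue test report, pooled across subjects.

    For each of the 8 manipulation labels: percent of probe go-responses
    directed at the trained rewarded category, with one- and two-tailed
    binomial tests against chance.
    """
    by_subject = _normalize_logs(logs)
    probes_by_label: dict[str, list[tuple[TrialRecord, StressPattern]]] = {
        m: [] for m in MANIPULATIONS if m != "none"
    }
    for subject, records in by_subject.items():
        phase_recs = [r for r in records if r.phase == "cue_test"]
        if len(phase_recs) != 240:
            raise ValueError(
                f"subject {subject}: cue test incomplete ({len(phase_recs)}/240 trials)"
            )
        pattern = _splus_pattern_of(phase_recs)
        for rec in phase_recs:
            if rec.role == "probe":
                probes_by_label[rec.stimulus["manipulation"]].append((rec, pattern))
    missing = [m for m, v in probes_by_label.items() if not v]
    if missing:
        raise ValueError(f"cue-test logs missing manipulation labels: {missing}")

    rows = []
    one_tailed: dict[str, BinomialResult] = {}
    two_tailed: dict[str, BinomialResult] = {}
    for label, tagged in probes_by_label.items():
        probes = [r for r, _ in tagged]
        patterns = [p for _, p in tagged]
        t1 = category_binomial(probes, patterns, tail="one")
        t2 = category_binomial(probes, patterns, tail="two")
        one_tailed[label] = t1
        two_tailed[label] = t2
        rows.append(
            {
                "manipulation": label,
                "n_probe_trials": len(probes),
                "n_go": t1.n,
                "x_correct": t1.x,
                "percent_correct": 100.0 * t1.x / t1.n if t1.n else float("nan"),
                "z": t1.z,
                "p_one_tailed": t1.p,
                "p_two_tailed": t2.p,
            }
        )
    return CueTestSummary(pd.DataFrame(rows), one_tailed, two_tailed)


@dataclass(frozen=True)
class CriterionTrace:
    trace: pd.DataFrame
    audit: pd.DataFrame | None


def criterion_trace(
    records: Sequence[TrialRecord],
    profile: SpeciesProfile | None = None,
    outcomes: Sequence[PhaseOutcome] | None = None,
) -> CriterionTrace:
    """Cumulative and per-session DR trajectories per phase.

    When phase outcomes (and the species profile) are supplied, each
    outcome's final DR and pass decision are recomputed from the raw
    records and compared; any mismatch is flagged in the audit table.
    """
    rows = []
    for phase in PHASE_ORDER:
        phase_recs = [r for r in records if r.phase == phase]
        window: list[TrialRecord] = []
        for i, rec in enumerate(phase_recs):
            window.append(rec)
            try:
                dr = discrimination_ratio(window).dr
            except ValueError:
                dr = None
            rows.append(
                {
                    "phase": phase,
                    "trial_in_phase": i + 1,
                    "session": rec.session,
                    "cumulative_dr": np.nan if dr is None else dr,
                }
            )
    trace = pd.DataFrame(rows)

    audit = None
    if outcomes is not None:
        if profile is None:
            raise ValueError("profile required to audit phase outcomes")
        audit_rows = []
        for outcome in outcomes:
            phase_recs = [r for r in records if r.phase == outcome.phase]
            try:
                recomputed = discrimination_ratio(phase_recs).dr
            except ValueError:
                recomputed = None
            session_drs = []
            if profile.sessioned:
                for s in sorted({r.session for r in phase_recs}):
                    sess = [r for r in phase_recs if r.session == s]
                    try:
                        session_drs.append(discrimination_ratio(sess).dr)
                    except ValueError:
                        session_drs.append(None)
            decision = phase_controller(
                profile,
                outcome.phase,
                cumulative_dr=recomputed,
                trials_used=len(phase_recs),
                session_drs=session_drs,
            )
            recomputed_passed = decision == "advance"
            dr_match = (
                (outcome.final_dr is None and recomputed is None)
                or (
                    outcome.final_dr is not None
                    and recomputed is not None
                    and np.isclose(outcome.final_dr, recomputed, rtol=0, atol=1e-12)
                )
            )
            audit_rows.append(
                {
                    "phase": outcome.phase,
                    "recorded_dr": outcome.final_dr,
                    "recomputed_dr": recomputed,
                    "dr_match": dr_match,
                    "recorded_passed": outcome.passed,
                    "recomputed_passed": recomputed_passed,
                    "passed_match": outcome.passed == recomputed_passed,
                }
            )
        audit = pd.DataFrame(audit_rows)
    return CriterionTrace(trace, audit)
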