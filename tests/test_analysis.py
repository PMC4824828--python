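"""Discrimination-ratio semantics and binomial test machinery."""

import numpy as np
import pytest
from scipy import stats

from stresslab.analysis import (
    category_binomial,
    criterion_trace,
    cue_test_report,
    discrimination_ratio,
    generalization_report,
)
from stresslab.lexicon import IAMBIC, TROCHAIC
from stresslab.observer import ObserverState, respond, PRESETS
from stresslab.schedule import BUDGERIGAR, HUMAN, PhaseOutcome, TrialRecord


def rec(role, responded, phase="discrimination", pattern=TROCHAIC, manipulation="none",
        trial=0, session=0):
    stim = {"kind": "word", "word": "puvo", "pattern": pattern, "manipulation": manipulation}
    if role in ("sound", "nosound"):
        stim = {"kind": "syllable"}
    return TrialRecord(trial, session, phase, role, stim, responded,
                       responded == (role in ("Splus", "sound")), "none", None)


def window(p_splus, p_sminus, n=100):
    """n/2 S+ and n/2 S- trials with the given response rates."""
    half = n // 2
    records = []
    for i in range(half):
        records.append(rec("Splus", i < round(p_splus * half), pattern=TROCHAIC))
        records.append(rec("Sminus", i < round(p_sminus * half), pattern=IAMBIC))
    return records


class TestDiscriminationRatio:
    def test_equal_responding_gives_half(self):
        result = discrimination_ratio(window(1.0, 1.0))
        assert result.dr == pytest.approx(0.5)
        assert result.percent_splus == result.percent_sminus == 100.0

    def test_perfect_discrimination_gives_one(self):
        assert discrimination_ratio(window(1.0, 0.0)).dr == pytest.approx(1.0)

    def test_60_20_gives_three_quarters(self):
        assert discrimination_ratio(window(0.6, 0.2)).dr == pytest.approx(0.75)

    def test_no_responding_is_flagged_undefined(self):
        result = discrimination_ratio(window(0.0, 0.0))
        assert result.undefined
        assert result.dr is None

    def test_window_without_sminus_rejected(self):
        with pytest.raises(ValueError):
            discrimination_ratio([rec("Splus", True)] * 10)

    def test_dr_in_unit_interval_and_half_iff_equal(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ps, pm = rng.integers(0, 11, 2) / 10
            result = discrimination_ratio(window(ps, pm))
            if result.dr is not None:
                assert 0.0 <= result.dr <= 1.0
                if ps == pm:
                    assert result.dr == pytest.approx(0.5)


def probe_records(x, n, n_trials=24, splus=TROCHAIC, phase="generalization"):
    """n go-responses to probes, x of them to the rewarded category."""
    sminus = IAMBIC if splus == TROCHAIC else TROCHAIC
    records = []
    for i in range(n_trials):
        to_splus = i < n_trials // 2
        idx = i if to_splus else i - n_trials // 2
        responded = (idx < x) if to_splus else (idx < n - x)
        records.append(rec("probe", responded, phase=phase,
                           pattern=splus if to_splus else sminus))
    return records


class TestCategoryBinomial:
    def test_all_responses_to_rewarded_category(self):
        result = category_binomial(probe_records(24, 24, 48), TROCHAIC)
        assert result.z == pytest.approx(4.899, abs=1e-3)

    def test_even_split_is_null_center(self):
        result = category_binomial(probe_records(12, 24, 48), TROCHAIC)
        assert result.z == 0.0
        assert result.p_exact > 0.5

    def test_exact_tail_18_of_20(self):
        result = category_binomial(probe_records(18, 20, 40), TROCHAIC)
        assert result.p_exact == pytest.approx(0.000201, abs=2e-6)
        assert result.p == result.p_exact  # exact authoritative below n=30

    def test_no_responses_flagged_undefined(self):
        result = category_binomial(probe_records(0, 0, 24), TROCHAIC)
        assert result.undefined
        assert np.isnan(result.z)

    def test_category_relabeling_symmetry(self):
        fwd = category_binomial(probe_records(18, 24, 48), TROCHAIC)
        rev = category_binomial(probe_records(18, 24, 48), IAMBIC)
        assert rev.x == fwd.n - fwd.x
        assert rev.z == pytest.approx(-fwd.z)

    def test_probe_trials_basis_counts_all_probes(self):
        result = category_binomial(probe_records(10, 12, 24), TROCHAIC, basis="probe_trials")
        assert result.n == 24
        # 10 correct gos + (12 - 2) correct withholds
        assert result.x == 10 + (24 // 2 - 2)

    def test_normal_approximation_tracks_exact_tail_for_large_n(self):
        """Continuity-corrected normal vs exact binomial, |dp| < 0.01, n >= 30."""
        from stresslab.analysis import _binomial_result

        for n in (30, 48, 96, 120):
            for x in range(n + 1):
                for tail in ("one", "two"):
                    r = _binomial_result(x, n, tail, "go_responses")
                    assert abs(r.p_normal_corrected - r.p_exact) < 0.01

    def test_pooled_z_grows_as_sqrt_k_on_identical_subjects(self):
        z1 = category_binomial(probe_records(18, 24, 48), TROCHAIC).z
        for k in (4, 9, 16):
            pooled = probe_records(18 * k, 24 * k, 48 * k)
            zk = category_binomial(pooled, TROCHAIC).z
            assert zk == pytest.approx(np.sqrt(k) * z1, rel=1e-9)


class TestTypeIError:
    @staticmethod
    def _guessing_rejection_rate(basis, n_sims=1000, seed=123):
        rng = np.random.default_rng(seed)
        profile = PRESETS["nonlearner"]
        state = ObserverState.initial(profile)
        rejections = 0
        for _ in range(n_sims):
            records = []
            for i in range(24):
                pattern = TROCHAIC if i < 12 else IAMBIC
                go = respond(pattern, state, profile, rng)
                records.append(rec("probe", go, phase="generalization", pattern=pattern))
            result = category_binomial(records, TROCHAIC, tail="one", basis=basis)
            if not result.undefined and result.p < 0.05:
                rejections += 1
        return rejections / n_sims

    def test_probe_trials_basis_is_calibrated_near_alpha(self):
        """Per-individual type-I error on guessing observers ~ alpha.

        Counting all 24 probe trials gives x ~ Bin(24, 1/2) under
        guessing; the exact one-tailed test at alpha = 0.05 has true
        level 0.032, so the empirical rate sits near (just under) alpha.
        """
        rate = self._guessing_rejection_rate("probe_trials")
        assert 0.015 <= rate <= 0.06

    def test_go_responses_basis_is_conservative_under_guessing(self):
        """With 12 probes per category, x given the number of go-responses
        is narrower than Bin(n, 1/2), so this basis over-covers: its
        false-positive rate must not exceed alpha."""
        rate = self._guessing_rejection_rate("go_responses")
        assert rate <= 0.05


class TestGeneralizationReport:
    def test_perfect_subject(self):
        # synthetic perfect subject: one S+ and one S- probe per block,
        # responds to every S+-category stimulus and never to S-
        records = []
        for i in range(12):
            records.append(rec("probe", True, phase="generalization", pattern=TROCHAIC))
            records.append(rec("probe", False, phase="generalization", pattern=IAMBIC))
            for j in range(4):
                records.append(rec("Splus", True, phase="generalization"))
                records.append(rec("Sminus", False, phase="generalization"))
        report = generalization_report([records])
        row = report.per_subject.iloc[0]
        assert row.novel_splus_pct == 100.0
        assert row.novel_sminus_pct == 0.0
        assert row.trained_splus_pct == 100.0
        assert row.z == pytest.approx(np.sqrt(12))

    def test_incomplete_phase_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            generalization_report([[rec("Splus", True, phase="generalization")]])

    def test_cohort_report_pools_counterbalanced_subjects(self, human_cohort_logs):
        report = generalization_report(human_cohort_logs)
        assert len(report.per_subject) == len(human_cohort_logs)
        # pooled counts are the sum of per-subject counts
        assert report.pooled.x == report.per_subject.x.sum()
        assert report.pooled.n == report.per_subject.n.sum()
        assert report.pooled.z > stats.norm.ppf(0.999)


class TestCueTestReport:
    def test_all_eight_labels_reported(self, human_cohort_logs):
        summary = cue_test_report(human_cohort_logs)
        assert len(summary.table) == 8
        assert summary.table.n_probe_trials.sum() == 48 * len(human_cohort_logs)
        assert (summary.table.n_probe_trials == 6 * len(human_cohort_logs)).all()

    def test_perfect_oracle_scores_100_everywhere(self):
        records = []
        manips = ["pitch_removed", "duration_removed", "amplitude_removed",
                  "vowel_removed", "pitch_only", "duration_only", "amplitude_only",
                  "vowel_only"]
        for b in range(24):
            manip = manips[b % 8]
            records.append(rec("probe", True, phase="cue_test", pattern=TROCHAIC,
                               manipulation=manip))
            records.append(rec("probe", False, phase="cue_test", pattern=IAMBIC,
                               manipulation=manip))
            for _ in range(4):
                records.append(rec("Splus", True, phase="cue_test"))
                records.append(rec("Sminus", False, phase="cue_test"))
        summary = cue_test_report([records])
        assert (summary.table.percent_correct == 100.0).all()

    def test_missing_label_rejected(self):
        records = []
        for b in range(24):
            records.append(rec("probe", True, phase="cue_test", pattern=TROCHAIC,
                               manipulation="pitch_removed"))
            records.append(rec("probe", False, phase="cue_test", pattern=IAMBIC,
                               manipulation="pitch_removed"))
            for _ in range(4):
                records.append(rec("Splus", True, phase="cue_test"))
                records.append(rec("Sminus", False, phase="cue_test"))
        with pytest.raises(ValueError, match="missing manipulation"):
            cue_test_report([records])


class TestCriterionTrace:
    def test_audit_agrees_for_simulated_budgerigar(self, budgie_cohort):
        result = next(r for r in budgie_cohort if r.completed)
        trace = criterion_trace(result.records, BUDGERIGAR, result.outcomes)
        assert trace.audit is not None
        assert trace.audit.dr_match.all()
        assert trace.audit.passed_match.all()
        # the discrimination advance happened exactly when the last 4
        # session DRs first all reached criterion
        discrim = [r for r in result.records if r.phase == "discrimination"]
        sessions = sorted({r.session for r in discrim})
        drs = []
        for s in sessions:
            sess = [r for r in discrim if r.session == s]
            drs.append(discrimination_ratio(sess).dr)
        runs = [i for i in range(3, len(drs)) if all(d >= 0.8 for d in drs[i - 3 : i + 1])]
        assert runs and runs[0] == len(drs) - 1

    def test_audit_agrees_for_human(self, human_cohort):
        result = next(r for r in human_cohort if r.completed)
        trace = criterion_trace(result.records, HUMAN, result.outcomes)
        assert trace.audit.dr_match.all()
        assert trace.audit.passed_match.all()

    def test_empty_log_gives_empty_trace(self):
        trace = criterion_trace([])
        assert trace.trace.empty

    def test_tampered_outcome_is_flagged(self, human_cohort):
        result = next(r for r in human_cohort if r.completed)
        outcome = result.outcomes[1]
        tampered = PhaseOutcome(outcome.phase, outcome.trials_used,
                                outcome.sessions_used, outcome.passed,
                                0.123456)
        trace = criterion_trace(result.records, HUMAN, [tampered])
        assert not trace.audit.dr_match.any()
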