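"""Acoustic contracts of the stimulus synthesizer."""

import itertools

import numpy as np
import pytest
from scipy import stats

from stresslab.lexicon import IAMBIC, TROCHAIC, Syllable, build_training_sets
from stresslab.synthesis import (
    CUES,
    MANIPULATIONS,
    StressCueParameters,
    Waveform,
    apply_manipulation,
    draw_cue_params,
    estimate_f0,
    load_formant_table,
    export_formant_table,
    default_formant_table,
    measure_rms,
    removed_cues,
    rms_to_db_attenuation,
    synthesize_syllable,
    synthesize_word,
    write_stimulus_bank,
)

FS = 44100


class TestDrawCueParams:
    def test_unstressed_pitch_is_flat_194(self, rng):
        for _ in range(20):
            p = draw_cue_params(False, rng)
            assert p.f0_start == p.f0_peak == 194.0
            assert p.vowel_mode == "reduced"

    def test_stressed_fixed_values(self, rng):
        for _ in range(20):
            p = draw_cue_params(True, rng)
            assert p.duration == 0.5
            assert p.rms_target == 0.1
            assert p.f0_start == 194.0
            assert 230.0 <= p.f0_peak <= 280.0
            assert p.vowel_mode == "full"

    def test_unstressed_draws_uniform_over_stated_intervals(self, rng):
        durations = np.array([draw_cue_params(False, rng).duration for _ in range(10_000)])
        rmss = np.array([draw_cue_params(False, rng).rms_target for _ in range(10_000)])
        assert 0.3 <= durations.min() and durations.max() <= 0.4
        assert 0.0316 <= rmss.min() and rmss.max() <= 0.0447
        assert stats.kstest(durations, stats.uniform(0.3, 0.1).cdf).pvalue > 0.01
        assert stats.kstest(rmss, stats.uniform(0.0316, 0.0447 - 0.0316).cdf).pvalue > 0.01


class TestApplyManipulation:
    @pytest.fixture()
    def pair(self, rng):
        return draw_cue_params(True, rng), draw_cue_params(False, rng)

    def test_none_is_identity(self, pair):
        assert apply_manipulation(*pair, "none") == pair

    def test_pitch_removed_flattens_both_contours(self, pair):
        s, u = apply_manipulation(*pair, "pitch_removed")
        assert s.f0_start == s.f0_peak == 194.0
        assert u.f0_start == u.f0_peak == 194.0
        # other cues untouched
        assert s.duration == pair[0].duration
        assert u.rms_target == pair[1].rms_target
        assert (s.vowel_mode, u.vowel_mode) == ("full", "reduced")

    @pytest.mark.parametrize(
        "label, attr, value",
        [
            ("duration_removed", "duration", 0.5),
            ("amplitude_removed", "rms_target", 0.1),
            ("vowel_removed", "vowel_mode", "full"),
        ],
    )
    def test_removal_gives_both_syllables_the_stressed_value(self, pair, label, attr, value):
        s, u = apply_manipulation(*pair, label)
        assert getattr(s, attr) == value
        assert getattr(u, attr) == value

    def test_only_equals_sequential_removal_of_other_three(self, pair):
        for cue in CUES:
            expected = pair
            for other in CUES:
                if other != cue:
                    expected = apply_manipulation(*expected, f"{other}_removed")
            assert apply_manipulation(*pair, f"{cue}_only") == expected

    def test_removals_idempotent_and_commutative(self, pair):
        for label in MANIPULATIONS:
            once = apply_manipulation(*pair, label)
            assert apply_manipulation(*once, label) == once
        for a, b in itertools.permutations([f"{c}_removed" for c in CUES], 2):
            ab = apply_manipulation(*apply_manipulation(*pair, a), b)
            ba = apply_manipulation(*apply_manipulation(*pair, b), a)
            assert ab == ba

    def test_unknown_label_rejected(self, pair):
        with pytest.raises(ValueError):
            apply_manipulation(*pair, "loudness_removed")
        with pytest.raises(ValueError):
            removed_cues("bogus")


class TestSynthesizeSyllable:
    @pytest.mark.parametrize("text", ["pu", "to", "ga", "mi", "zi", "ji", "de", "lu"])
    def test_duration_rms_and_f0_contracts(self, rng, text):
        syll = Syllable.from_text(text)
        for stressed in (True, False):
            p = draw_cue_params(stressed, rng)
            w = synthesize_syllable(syll, p, FS)
            assert abs(w.samples.size - round(p.duration * FS)) <= 1
            assert abs(measure_rms(w) / p.rms_target - 1) < 0.01
            voiced = estimate_f0(w).voiced_values
            assert voiced.size > 0
            if stressed:
                # terminal frame averages the rising ramp over its window
                assert voiced[-1] >= 230.0 - 6.0
                assert voiced[-1] <= 280.0 + 3.0
            else:
                assert abs(np.median(voiced) - 194.0) <= 2.0

    def test_stressed_terminal_f0_tracks_drawn_peak(self, rng):
        p = draw_cue_params(True, rng)
        w = synthesize_syllable(Syllable.from_text("na"), p, FS)
        voiced = estimate_f0(w).voiced_values
        # expected mean f0 over the final 40 ms frame of the linear ramp
        expected = p.f0_start + (p.f0_peak - p.f0_start) * (p.duration - 0.02) / p.duration
        assert abs(voiced[-1] - expected) <= 3.0

    def test_no_clipping_headroom(self, rng):
        for text in ("pu", "su", "ke"):
            p = draw_cue_params(True, rng)
            w = synthesize_syllable(Syllable.from_text(text), p, FS)
            assert np.max(np.abs(w.samples)) < 1.0

    def test_too_short_duration_rejected(self):
        p = StressCueParameters(194.0, 194.0, 0.05, 0.04, "reduced")
        with pytest.raises(ValueError):
            synthesize_syllable(Syllable.from_text("pu"), p, FS)


class TestSynthesizeWord:
    def test_trochaic_duration_is_half_second_plus_unstressed(self, rng):
        word = build_training_sets()[0].words[0]  # puvo
        stim = synthesize_word(word, TROCHAIC, "none", rng, FS)
        u = stim.audio.duration - 0.5
        assert 0.3 - 2 / FS <= u <= 0.4 + 2 / FS
        assert stim.audio.duration == pytest.approx(
            sum(p.duration for p in stim.syllable_params), abs=2 / FS
        )

    def test_duration_removed_word_lasts_one_second(self, rng):
        word = build_training_sets()[0].words[0]
        stim = synthesize_word(word, IAMBIC, "duration_removed", rng, FS)
        assert abs(stim.audio.samples.size - FS) <= 2

    def test_pattern_swaps_stressed_slot(self, rng):
        word = build_training_sets()[0].words[0]
        tro = synthesize_word(word, TROCHAIC, "none", rng, FS)
        iam = synthesize_word(word, IAMBIC, "none", rng, FS)
        assert tro.syllable_params[0].duration == 0.5  # stressed first
        assert iam.syllable_params[1].duration == 0.5  # stressed second
        assert tro.stressed_slot == 0 and iam.stressed_slot == 1


class TestMeasurement:
    def test_rms_closed_forms(self):
        assert measure_rms(Waveform(np.full(1000, 0.1), FS)) == pytest.approx(0.1)
        t = np.arange(FS) / FS
        sine = Waveform(np.sin(2 * np.pi * 100 * t), FS)
        assert measure_rms(sine) == pytest.approx(1 / np.sqrt(2), abs=1e-3)
        with pytest.raises(ValueError):
            measure_rms(Waveform(np.empty(0), FS))

    def test_db_attenuation_matches_stated_rms_bounds(self):
        assert rms_to_db_attenuation(0.1, 0.1) == pytest.approx(0.0)
        assert rms_to_db_attenuation(0.1, 0.0316) == pytest.approx(10.0, abs=0.05)
        assert rms_to_db_attenuation(0.1, 0.0447) == pytest.approx(7.0, abs=0.05)
        with pytest.raises(ValueError):
            rms_to_db_attenuation(0.0, 0.1)

    def test_f0_estimator_on_known_tone_and_silence(self):
        t = np.arange(int(0.5 * FS)) / FS
        tone = Waveform(0.8 * np.sin(2 * np.pi * 194 * t), FS)
        voiced = estimate_f0(tone).voiced_values
        assert np.all(np.abs(voiced - 194.0) <= 1.0)
        silence = estimate_f0(Waveform(np.zeros(FS // 2), FS))
        assert silence.is_empty


class TestStimulusBank:
    def test_training_bank_counts_and_determinism(self, tmp_path, word_sets):
        s1, _ = word_sets
        m1 = write_stimulus_bank(s1, 7, tmp_path / "a")
        m2 = write_stimulus_bank(s1, 7, tmp_path / "b")
        assert len(m1) == 24
        for fname in m1.filename:
            assert (tmp_path / "a" / fname).read_bytes() == (tmp_path / "b" / fname).read_bytes()

    def test_probe_bank_has_48_stimuli(self, tmp_path, word_sets):
        s1, _ = word_sets
        manips = [m for m in MANIPULATIONS if m != "none"]
        manifest = write_stimulus_bank(s1, 7, tmp_path / "probes", manipulations=manips)
        assert len(manifest) == 48
        counts = manifest.groupby(["manipulation", "pattern"]).size()
        assert (counts == 3).all()

    def test_manifest_parameter_recovery(self, tmp_path, word_sets):
        """Measured duration/RMS/f0 of bank files match their manifest rows."""
        from scipy.io import wavfile

        s1, _ = word_sets
        manifest = write_stimulus_bank(s1, 11, tmp_path / "bank")
        for _, row in manifest.head(6).iterrows():
            fs, data = wavfile.read(tmp_path / "bank" / row.filename)
            w = Waveform(data / 32767.0, fs)
            assert w.duration == pytest.approx(row.duration1 + row.duration2, abs=2 / fs)
            n1 = int(round(row.duration1 * fs))
            assert measure_rms(w.samples[:n1]) == pytest.approx(row.rms1, rel=0.02)
            assert measure_rms(w.samples[n1:]) == pytest.approx(row.rms2, rel=0.02)
            stressed_slot = 0 if row.pattern == "trochaic" else 1
            seg = w.samples[:n1] if stressed_slot == 0 else w.samples[n1:]
            voiced = estimate_f0(Waveform(seg, fs)).voiced_values
            peak = row.f0_peak1 if stressed_slot == 0 else row.f0_peak2
            assert voiced[-1] == pytest.approx(peak, abs=6.0)


def test_formant_table_csv_round_trip(tmp_path):
    path = tmp_path / "formants.csv"
    export_formant_table(path)
    assert load_formant_table(path) == default_formant_table()
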