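"""Parametric synthesis of stress-cued syllables and nonsense words.

Lexical stress is simulated by four acoustic cues, each with fixed
stressed/unstressed target values:

==========  ==========================  ================================
cue         stressed                    unstressed
==========  ==========================  ================================
pitch       f0 rises linearly from      flat 194 Hz
            194 Hz to a peak drawn
            uniformly in [230, 280] Hz
duration    0.5 s                       uniform in [0.3, 0.4] s
amplitude   RMS 0.1                     RMS uniform in [0.0316, 0.0447]
                                        (7-10 dB below stressed)
vowel       full (long) vowel           reduced vowel (schwa or lax)
==========  ==========================  ================================

Audio is produced by source-filter formant synthesis: an impulse-train
(voiced) or noise (obstruent) source shaped by spectral tilt, passed
through a cascade of second-order formant resonators, with stylized
consonant onsets.  No recorded speech is involved, so every stimulus is
reproducible bit-for-bit from a seed.

Cue-removal probes neutralize one cue (or all but one) by giving both
syllables the same value on that cue: the stressed value for duration,
amplitude and vowel quality, the unstressed flat contour for pitch.
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

from .lexicon import (
    IAMBIC,
    TROCHAIC,
    NonsenseWord,
    StressPattern,
    Syllable,
    WordSet,
    vowel_realization,
)

__all__ = [
    "StressCueParameters",
    "Waveform",
    "WordStimulus",
    "SyllableStimulus",
    "F0Track",
    "MANIPULATIONS",
    "CUES",
    "removed_cues",
    "draw_cue_params",
    "apply_manipulation",
    "draw_word_parameters",
    "synthesize_syllable",
    "synthesize_word",
    "measure_rms",
    "rms_to_db_attenuation",
    "estimate_f0",
    "write_stimulus_bank",
    "default_formant_table",
    "export_formant_table",
    "load_formant_table",
]

DEFAULT_SAMPLE_RATE = 44100

F0_BASE = 194.0
F0_PEAK_RANGE = (230.0, 280.0)
STRESSED_DURATION = 0.5
UNSTRESSED_DURATION_RANGE = (0.3, 0.4)
STRESSED_RMS = 0.1
UNSTRESSED_RMS_RANGE = (0.0316, 0.0447)

#: Shortest synthesizable syllable: the consonant onset plus a usable
#: voiced vowel portion.
MIN_SYLLABLE_DURATION = 0.1

CUES = ("pitch", "duration", "amplitude", "vowel")

MANIPULATIONS = (
    "none",
    "pitch_removed",
    "duration_removed",
    "amplitude_removed",
    "vowel_removed",
    "pitch_only",
    "duration_only",
    "amplitude_only",
    "vowel_only",
)


def removed_cues(manipulation: str) -> frozenset[str]:
    """The set of cues neutralized by a manipulation label.

    ``"X_only"`` is equivalent to removing the other three cues;
    ``"none"`` removes nothing.
    """
    if manipulation not in MANIPULATIONS:
        raise ValueError(f"unknown manipulation {manipulation!r}")
    if manipulation == "none":
        return frozenset()
    cue, _, kind = manipulation.rpartition("_")
    if kind == "removed":
        return frozenset([cue])
    return frozenset(c for c in CUES if c != cue)


@dataclass(frozen=True)
class StressCueParameters:
    """Acoustic targets for one syllable token."""

    f0_start: float
    f0_peak: float
    duration: float
    rms_target: float
    vowel_mode: str  # "full" | "reduced"

    def __post_init__(self) -> None:
        if self.vowel_mode not in ("full", "reduced"):
            raise ValueError(f"vowel_mode must be 'full' or 'reduced', got {self.vowel_mode!r}")
        if self.duration <= 0 or self.rms_target <= 0:
            raise ValueError("duration and rms_target must be positive")


@dataclass(frozen=True)
class Waveform:
    """Sampled mono audio."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.samples.size and np.max(np.abs(self.samples)) > 1.0:
            raise ValueError("waveform samples exceed [-1, 1]")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def concatenate(self, other: "Waveform") -> "Waveform":
        if other.sample_rate != self.sample_rate:
            raise ValueError("sample-rate mismatch")
        return Waveform(np.concatenate([self.samples, other.samples]), self.sample_rate)


@dataclass(frozen=True)
class SyllableStimulus:
    """A single-syllable stimulus (preliminary-training material)."""

    syllable: Syllable
    stressed: bool
    params: StressCueParameters


@dataclass(frozen=True)
class WordStimulus:
    """A two-syllable stimulus with its drawn per-syllable parameters.

    ``syllable_params`` follows slot order (first syllable, second
    syllable); ``audio`` is None for parameter-only descriptors used in
    fast simulation.
    """

    word: NonsenseWord
    pattern: StressPattern
    manipulation: str
    syllable_params: tuple[StressCueParameters, StressCueParameters]
    audio: Waveform | None = None

    @property
    def stressed_slot(self) -> int:
        return 0 if self.pattern == TROCHAIC else 1


def draw_cue_params(stressed: bool, rng: np.random.Generator) -> StressCueParameters:
    """Draw one syllable's cue parameters for the given stress state.

    Randomized quantities (stressed f0 peak; unstressed duration and RMS)
    are uniform over their intervals and independent per draw.
    """
    if stressed:
        return StressCueParameters(
            f0_start=F0_BASE,
            f0_peak=float(rng.uniform(*F0_PEAK_RANGE)),
            duration=STRESSED_DURATION,
            rms_target=STRESSED_RMS,
            vowel_mode="full",
        )
    return StressCueParameters(
        f0_start=F0_BASE,
        f0_peak=F0_BASE,
        duration=float(rng.uniform(*UNSTRESSED_DURATION_RANGE)),
        rms_target=float(rng.uniform(*UNSTRESSED_RMS_RANGE)),
        vowel_mode="reduced",
    )


def apply_manipulation(
    stressed_params: StressCueParameters,
    unstressed_params: StressCueParameters,
    manipulation: str,
) -> tuple[StressCueParameters, StressCueParameters]:
    """Neutralize the removed cues on both syllables.

    Removal gives both syllables the same value: flat 194 Hz contour for
    pitch, 0.5 s for duration, RMS 0.1 for amplitude, the full vowel for
    vowel quality.  Removals of distinct cues commute, and each removal is
    idempotent.
    """
    removed = removed_cues(manipulation)
    s, u = stressed_params, unstressed_params
    if "pitch" in removed:
        s = replace(s, f0_start=F0_BASE, f0_peak=F0_BASE)
        u = replace(u, f0_start=F0_BASE, f0_peak=F0_BASE)
    if "duration" in removed:
        s = replace(s, duration=STRESSED_DURATION)
        u = replace(u, duration=STRESSED_DURATION)
    if "amplitude" in removed:
        s = replace(s, rms_target=STRESSED_RMS)
        u = replace(u, rms_target=STRESSED_RMS)
    if "vowel" in removed:
        s = replace(s, vowel_mode="full")
        u = replace(u, vowel_mode="full")
    return s, u


def draw_word_parameters(
    word: NonsenseWord,
    pattern: StressPattern,
    manipulation: str = "none",
    rng: np.random.Generator | None = None,
) -> WordStimulus:
    """Draw per-syllable parameters for a word without rendering audio."""
    if pattern not in (TROCHAIC, IAMBIC):
        raise ValueError(f"unknown stress pattern {pattern!r}")
    rng = np.random.default_rng() if rng is None else rng
    stressed = draw_cue_params(True, rng)
    unstressed = draw_cue_params(False, rng)
    stressed, unstressed = apply_manipulation(stressed, unstressed, manipulation)
    params = (stressed, unstressed) if pattern == TROCHAIC else (unstressed, stressed)
    return WordStimulus(word, pattern, manipulation, params, audio=None)


# ---------------------------------------------------------------------------
# formant targets
# ---------------------------------------------------------------------------

#: F1-F3 targets (Hz) per IPA vowel, as one or two target frames (two
#: frames = diphthong rendered as a crossfaded glide).  Values are typical
#: of an adult female speaker, consistent with the 194 Hz base f0.
_FORMANT_TABLE: dict[str, tuple[tuple[float, float, float], ...]] = {
    "ɔ": ((700.0, 1100.0, 2800.0),),
    "ə": ((550.0, 1550.0, 2750.0),),
    "eɪ": ((480.0, 2330.0, 2930.0), (430.0, 2480.0, 3070.0)),
    "ε": ((610.0, 2050.0, 2850.0),),
    "i:": ((310.0, 2790.0, 3310.0),),
    "ɪ": ((430.0, 2480.0, 3070.0),),
    "oʊ": ((500.0, 1050.0, 2800.0), (440.0, 1020.0, 2750.0)),
    "u:": ((370.0, 950.0, 2670.0),),
}

FORMANT_BANDWIDTHS = (90.0, 120.0, 170.0)


def default_formant_table() -> dict[str, tuple[tuple[float, float, float], ...]]:
    """Copy of the built-in vowel formant target table."""
    return dict(_FORMANT_TABLE)


def export_formant_table(path: str | Path) -> None:
    """Write the formant table as CSV (ipa, F1, F2, F3, B1, B2, B3).

    Diphthongs occupy consecutive rows with the same IPA label.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ipa", "F1", "F2", "F3", "B1", "B2", "B3"])
        for ipa, frames in _FORMANT_TABLE.items():
            for f1, f2, f3 in frames:
                writer.writerow([ipa, f1, f2, f3, *FORMANT_BANDWIDTHS])


def load_formant_table(path: str | Path) -> dict[str, tuple[tuple[float, float, float], ...]]:
    """Read a formant table CSV written by :func:`export_formant_table`."""
    table: dict[str, list[tuple[float, float, float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table.setdefault(row["ipa"], []).append(
                (float(row["F1"]), float(row["F2"]), float(row["F3"]))
            )
    return {k: tuple(v) for k, v in table.items()}


# ---------------------------------------------------------------------------
# consonant onset styles
# ---------------------------------------------------------------------------

# kind: voiceless_stop | voiced_stop | nasal | fricative_voiceless |
#       fricative_voiced | glide | liquid
# band: burst/frication band-pass edges (Hz) where applicable
# formants: resonator targets for sonorant onsets
_CONSONANTS: dict[str, dict] = {
    "p": {"kind": "voiceless_stop", "band": (400.0, 1400.0)},
    "t": {"kind": "voiceless_stop", "band": (2500.0, 4800.0)},
    "k": {"kind": "voiceless_stop", "band": (1400.0, 2800.0)},
    "g": {"kind": "voiced_stop", "band": (1400.0, 2800.0)},
    "d": {"kind": "voiced_stop", "band": (2500.0, 4800.0)},
    "m": {"kind": "nasal", "formants": (250.0, 1100.0, 2200.0)},
    "n": {"kind": "nasal", "formants": (280.0, 1400.0, 2400.0)},
    "s": {"kind": "fricative_voiceless", "band": (3200.0, 4900.0)},
    "z": {"kind": "fricative_voiced", "band": (3200.0, 4900.0)},
    "v": {"kind": "fricative_voiced", "band": (700.0, 2200.0)},
    "j": {"kind": "glide", "formants": (310.0, 2790.0, 3310.0)},
    "l": {"kind": "liquid", "formants": (360.0, 1100.0, 2700.0)},
}

_EDGE_RAMP = 0.005  # raised-cosine edge ramps, s
_XFADE = 0.010  # consonant->vowel crossfade, s


def _resonator_coeffs(freq: float, bandwidth: float, fs: int):
    r = np.exp(-np.pi * bandwidth / fs)
    c = -(r * r)
    b = 2.0 * r * np.cos(2.0 * np.pi * freq / fs)
    a = 1.0 - b - c
    return [a], [1.0, -b, -c]


def _formant_cascade(x: np.ndarray, formants: Sequence[float], fs: int) -> np.ndarray:
    y = x
    for freq, bw in zip(formants, FORMANT_BANDWIDTHS):
        b, a = _resonator_coeffs(freq, bw, fs)
        y = sps.lfilter(b, a, y)
    return y


def _tilted_impulse_train(
    n: int, voiced_from: int, f0_start: float, f0_peak: float, fs: int
) -> np.ndarray:
    """Impulse train with a linear f0 ramp over the voiced span, shaped by
    glottal spectral tilt (two one-pole lowpasses) and DC-blocked."""
    src = np.zeros(n)
    m = n - voiced_from
    if m > 0:
        f = np.linspace(f0_start, f0_peak, m)
        phase = np.cumsum(f) / fs
        ticks = np.floor(phase)
        hits = np.flatnonzero(np.diff(np.concatenate([[0.0], ticks])) >= 1.0)
        src[voiced_from + hits] = 1.0
    src = sps.lfilter([1.0], [1.0, -0.96], src)
    src = sps.lfilter([1.0], [1.0, -0.96], src)
    src = sps.lfilter([1.0, -1.0], [1.0, -0.995], src)  # DC block
    return src


def _bandpass_noise(n: int, band: tuple[float, float], fs: int, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(n)
    lo, hi = band
    sos = sps.butter(2, [lo / (fs / 2), hi / (fs / 2)], btype="band", output="sos")
    return sps.sosfilt(sos, noise)


def _raised_cosine_edges(y: np.ndarray, fs: int, ramp: float = _EDGE_RAMP) -> np.ndarray:
    k = min(int(round(ramp * fs)), y.size // 2)
    if k > 0:
        w = 0.5 * (1.0 - np.cos(np.pi * np.arange(k) / k))
        y = y.copy()
        y[:k] *= w
        y[-k:] *= w[::-1]
    return y


def _stable_noise_rng(syll: Syllable, params: StressCueParameters) -> np.random.Generator:
    # Consonant noise must be deterministic per (syllable, parameter) token
    # so that a seeded bank regenerates bit-identically.
    key = f"{syll.text}|{params.f0_peak:.6f}|{params.duration:.6f}|{params.rms_target:.6f}|{params.vowel_mode}"
    return np.random.default_rng(zlib.crc32(key.encode()))


def synthesize_syllable(
    syll: Syllable,
    params: StressCueParameters,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> Waveform:
    """Render one syllable.

    Contracts: output length equals ``params.duration`` to within one
    sample; overall RMS equals ``params.rms_target`` to within 1 %
    relative; f0 over the voiced region ramps linearly from ``f0_start``
    to ``f0_peak`` (peak at syllable end); the vowel's formants realize
    the full or reduced IPA vowel per the pronunciation table.
    """
    fs = int(sample_rate)
    if params.duration < MIN_SYLLABLE_DURATION:
        raise ValueError(
            f"duration {params.duration} s below minimum {MIN_SYLLABLE_DURATION} s "
            "(consonant onset would not fit)"
        )
    n = int(round(params.duration * fs))
    n_onset = int(round(min(0.06, 0.2 * params.duration) * fs))
    n_xf = min(int(round(_XFADE * fs)), n - n_onset)

    cons = _CONSONANTS[syll.onset]
    kind = cons["kind"]
    voiceless_onset = kind in ("voiceless_stop", "fricative_voiceless")
    voiced_from = n_onset if voiceless_onset else 0

    src = _tilted_impulse_train(n, voiced_from, params.f0_start, params.f0_peak, fs)
    noise_rng = _stable_noise_rng(syll, params)

    # --- vowel part -------------------------------------------------------
    ipa = vowel_realization(syll.vowel, stressed=(params.vowel_mode == "full"))
    frames = _FORMANT_TABLE[ipa]
    if len(frames) == 1:
        vowel = _formant_cascade(src, frames[0], fs)
    else:
        a = _formant_cascade(src, frames[0], fs)
        b = _formant_cascade(src, frames[1], fs)
        # diphthong: crossfade first target into second over the vowel span
        w = np.zeros(n)
        span = max(n - n_onset, 1)
        w[n_onset:] = np.linspace(0.0, 1.0, n - n_onset)
        vowel = (1.0 - w) * a + w * b
    peak = np.max(np.abs(vowel))
    if peak > 0:
        vowel = vowel / peak

    # --- consonant part ---------------------------------------------------
    cpart = np.zeros(n)
    span = n_onset + n_xf
    if kind in ("voiceless_stop", "voiced_stop"):
        n_burst = min(int(round(0.012 * fs)), span)
        burst = _bandpass_noise(n_burst, cons["band"], fs, noise_rng)
        start = max(n_onset - n_burst, 0)
        cpart[start : start + n_burst] = burst
        if kind == "voiced_stop":
            # low-frequency voicing murmur during closure
            b, a = _resonator_coeffs(180.0, 120.0, fs)
            murmur = sps.lfilter(b, a, src)
            mpk = np.max(np.abs(murmur[:span])) or 1.0
            cpart[:start] += 0.4 * murmur[:start] / mpk
    elif kind in ("fricative_voiceless", "fricative_voiced"):
        fric = _bandpass_noise(span, cons["band"], fs, noise_rng)
        fpk = np.max(np.abs(fric)) or 1.0
        cpart[:span] = fric / fpk
        if kind == "fricative_voiced":
            b, a = _resonator_coeffs(200.0, 120.0, fs)
            murmur = sps.lfilter(b, a, src)
            mpk = np.max(np.abs(murmur[:span])) or 1.0
            cpart[:span] = 0.6 * cpart[:span] + 0.5 * murmur[:span] / mpk
    else:  # nasal, glide, liquid: sonorant onset through its own formants
        son = _formant_cascade(src, cons["formants"], fs)
        spk = np.max(np.abs(son[:span])) or 1.0
        cpart[:span] = son[:span] / spk
    cpk = np.max(np.abs(cpart))
    if cpk > 0:
        cpart = cpart / cpk

    # --- mix with crossfade ----------------------------------------------
    w_vowel = np.ones(n)
    w_vowel[:n_onset] = 0.0
    if n_xf > 0:
        w_vowel[n_onset : n_onset + n_xf] = 0.5 * (
            1.0 - np.cos(np.pi * np.arange(n_xf) / n_xf)
        )
    y = w_vowel * vowel + 0.45 * (1.0 - w_vowel) * cpart

    y = _raised_cosine_edges(y, fs)
    rms = float(np.sqrt(np.mean(y**2)))
    if rms <= 0:
        raise ValueError("degenerate silent synthesis output")
    y *= params.rms_target / rms
    peak = np.max(np.abs(y))
    if peak >= 1.0:  # pragma: no cover - defensive; crest factors stay < 10
        y *= 0.99 / peak
    return Waveform(y, fs)


def synthesize_word(
    word: NonsenseWord,
    pattern: StressPattern,
    manipulation: str = "none",
    rng: np.random.Generator | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> WordStimulus:
    """Render a two-syllable word stimulus: draw cue parameters, apply the
    manipulation, synthesize both syllables and concatenate with no gap."""
    stim = draw_word_parameters(word, pattern, manipulation, rng)
    first = synthesize_syllable(word.first, stim.syllable_params[0], sample_rate)
    second = synthesize_syllable(word.second, stim.syllable_params[1], sample_rate)
    return WordStimulus(
        word, pattern, manipulation, stim.syllable_params, first.concatenate(second)
    )


# ---------------------------------------------------------------------------
# acoustic measurement
# ---------------------------------------------------------------------------


def measure_rms(w: Waveform | np.ndarray) -> float:
    """Root-mean-square amplitude, sqrt(mean(sample^2))."""
    x = w.samples if isinstance(w, Waveform) else np.asarray(w, dtype=float)
    if x.size == 0:
        raise ValueError("empty waveform")
    return float(np.sqrt(np.mean(x**2)))


def rms_to_db_attenuation(rms_a: float, rms_b: float) -> float:
    """Level difference 20*log10(rms_a / rms_b) in dB."""
    if rms_a <= 0 or rms_b <= 0:
        raise ValueError("RMS values must be positive")
    return 20.0 * np.log10(rms_a / rms_b)


@dataclass(frozen=True)
class F0Track:
    """Frame-wise f0 estimates; NaN marks unvoiced frames."""

    times: np.ndarray
    f0: np.ndarray

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)

    @property
    def voiced_values(self) -> np.ndarray:
        return self.f0[self.voiced]

    @property
    def is_empty(self) -> bool:
        return not bool(self.voiced.any())


def estimate_f0(
    w: Waveform,
    frame_length: float = 0.040,
    hop: float = 0.010,
    fmin: float = 120.0,
    fmax: float = 350.0,
    voicing_threshold: float = 0.35,
) -> F0Track:
    """Autocorrelation f0 tracker.

    Each frame's normalized autocorrelation is searched over the lag range
    corresponding to [fmin, fmax]; the earliest peak within 95 % of the
    maximum is chosen (guards against octave-down errors) and refined by
    parabolic interpolation.  Frames with low energy or a weak peak are
    flagged unvoiced (NaN).
    """
    x = w.samples
    fs = w.sample_rate
    nf = int(round(frame_length * fs))
    nh = max(int(round(hop * fs)), 1)
    if x.size < nf:
        return F0Track(np.empty(0), np.empty(0))
    lag_min = int(np.floor(fs / fmax))
    lag_max = int(np.ceil(fs / fmin))
    global_rms = measure_rms(x) if x.size else 0.0

    times, f0s = [], []
    for start in range(0, x.size - nf + 1, nh):
        frame = x[start : start + nf]
        frame = frame - np.mean(frame)
        times.append((start + nf / 2) / fs)
        frms = np.sqrt(np.mean(frame**2))
        if global_rms == 0 or frms < 0.05 * global_rms:
            f0s.append(np.nan)
            continue
        r = np.correlate(frame, frame, mode="full")[nf - 1 :]
        if r[0] <= 0:
            f0s.append(np.nan)
            continue
        r = r / r[0]
        # undo the linear taper of the biased autocorrelation so peak
        # positions are not pulled toward shorter lags
        r = r * (nf / (nf - np.arange(nf)))
        hi = min(lag_max + 1, r.size - 1)
        seg = r[lag_min:hi]
        if seg.size == 0:
            f0s.append(np.nan)
            continue
        best = float(np.max(seg))
        if best < voicing_threshold:
            f0s.append(np.nan)
            continue
        # earliest near-maximal *local* peak avoids octave-down errors
        # without sliding onto the rising flank of the main peak
        interior = np.flatnonzero(
            (seg[1:-1] >= seg[:-2]) & (seg[1:-1] >= seg[2:]) & (seg[1:-1] >= 0.95 * best)
        )
        if interior.size:
            lag = lag_min + 1 + int(interior[0])
        else:
            lag = lag_min + int(np.argmax(seg))
        if 0 < lag < r.size - 1:
            y0, y1, y2 = r[lag - 1], r[lag], r[lag + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            lag_refined = lag + float(np.clip(delta, -1, 1))
        else:
            lag_refined = float(lag)
        f0s.append(fs / lag_refined)
    return F0Track(np.asarray(times), np.asarray(f0s))


# ---------------------------------------------------------------------------
# stimulus bank
# ---------------------------------------------------------------------------


def _wav_int16(w: Waveform) -> np.ndarray:
    return np.clip(np.round(w.samples * 32767.0), -32768, 32767).astype(np.int16)


def write_stimulus_bank(
    word_set: WordSet,
    seed: int,
    out_dir: str | Path,
    manipulations: Iterable[str] = ("none",),
    exemplars_per_manipulation: int = 3,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> "pd.DataFrame":
    """Render a seeded stimulus bank to WAV files plus a CSV manifest.

    With ``manipulations=("none",)`` (default) every word x pattern
    combination is rendered once: 24 files for a 12-word set.  Each
    non-trivial manipulation instead contributes
    ``exemplars_per_manipulation`` randomly drawn word exemplars per
    stress pattern (3 x 8 x 2 = 48 probe files for the full cue-test
    bank).  Regeneration with the same seed is bit-identical.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for manipulation in manipulations:
        if manipulation not in MANIPULATIONS:
            raise ValueError(f"unknown manipulation {manipulation!r}")
        for pattern in (TROCHAIC, IAMBIC):
            if manipulation == "none":
                jobs = [(w, 0) for w in word_set.words]
            else:
                idx = rng.choice(len(word_set.words), size=exemplars_per_manipulation, replace=False)
                jobs = [(word_set.words[int(i)], k) for k, i in enumerate(idx)]
            for word, exemplar in jobs:
                stim = synthesize_word(word, pattern, manipulation, rng, sample_rate)
                fname = f"{word.text}_{pattern}_{manipulation}_{exemplar}.wav"
                wavfile.write(out / fname, sample_rate, _wav_int16(stim.audio))
                p1, p2 = stim.syllable_params
                rows.append(
                    {
                        "filename": fname,
                        "word": word.text,
                        "pattern": pattern,
                        "manipulation": manipulation,
                        "exemplar": exemplar,
                        "f0_peak1": p1.f0_peak,
                        "f0_peak2": p2.f0_peak,
                        "duration1": p1.duration,
                        "duration2": p2.duration,
                        "rms1": p1.rms_target,
                        "rms2": p2.rms_target,
                        "vowel_mode1": p1.vowel_mode,
                        "vowel_mode2": p2.vowel_mode,
                        "seed": seed,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
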