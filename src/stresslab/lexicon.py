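"""Nonsense-word inventory for the lexical-stress discrimination task.

Two disjoint sets of 12 two-syllable CV-CV nonsense words are used: one as
the training set, the other as the novel-word generalization probe set
(assignment counterbalanced across subjects).  Each set is built from six
syllables, and each syllable occurs in exactly four words of its set —
twice word-initially and twice word-finally — so that syllable identity
alone carries no information about the stress pattern.

Every word exists in two stress realizations: trochaic (first syllable
stressed) and iambic (second syllable stressed).  Stress is carried by four
acoustic cues (pitch, amplitude, duration, vowel quality); the vowel-quality
cue is realized by substituting a full vowel in stressed position for a
reduced one (mostly schwa) in unstressed position, per the fixed
pronunciation table below.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "Syllable",
    "NonsenseWord",
    "WordSet",
    "VowelRealization",
    "StressPattern",
    "TROCHAIC",
    "IAMBIC",
    "VOWELS",
    "VOWEL_TABLE",
    "build_training_sets",
    "vowel_realization",
    "validate_set",
    "consonant_inventory",
    "export_wordsets_csv",
    "import_wordsets_csv",
]

VOWELS = ("A", "E", "I", "O", "U")

#: Pronunciation of each orthographic vowel: (stressed IPA, unstressed IPA).
#: Stressed realizations are full/long vowels; unstressed are reduced
#: (schwa or lax counterparts).
VOWEL_TABLE: dict[str, tuple[str, str]] = {
    "A": ("ɔ", "ə"),
    "E": ("eɪ", "ε"),
    "I": ("i:", "ɪ"),
    "O": ("oʊ", "ə"),
    "U": ("u:", "ə"),
}

StressPattern = Literal["trochaic", "iambic"]
TROCHAIC: StressPattern = "trochaic"
IAMBIC: StressPattern = "iambic"


@dataclass(frozen=True)
class Syllable:
    """A CV syllable: consonant onset + orthographic vowel letter."""

    onset: str
    vowel: str

    def __post_init__(self) -> None:
        if self.vowel not in VOWELS:
            raise ValueError(f"unknown vowel {self.vowel!r}; expected one of {VOWELS}")
        if not (len(self.onset) == 1 and self.onset.isalpha() and self.onset.islower()):
            raise ValueError(f"onset must be a single lowercase consonant, got {self.onset!r}")

    @classmethod
    def from_text(cls, text: str) -> "Syllable":
        """Parse a two-character syllable like ``"pu"``."""
        if len(text) != 2:
            raise ValueError(f"syllable text must be 2 characters, got {text!r}")
        return cls(onset=text[0], vowel=text[1].upper())

    @property
    def text(self) -> str:
        return self.onset + self.vowel.lower()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class NonsenseWord:
    """An ordered pair of syllables drawn from a single training set."""

    first: Syllable
    second: Syllable
    set_id: int

    def __post_init__(self) -> None:
        if self.set_id not in (1, 2):
            raise ValueError("set_id must be 1 or 2")
        if self.first == self.second:
            raise ValueError("a word's two syllables must differ")

    @classmethod
    def from_text(cls, text: str, set_id: int) -> "NonsenseWord":
        if len(text) != 4:
            raise ValueError(f"word text must be 4 characters, got {text!r}")
        return cls(Syllable.from_text(text[:2]), Syllable.from_text(text[2:]), set_id)

    @property
    def text(self) -> str:
        return self.first.text + self.second.text

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class WordSet:
    """One of the two 12-word lists, with its 6-syllable inventory."""

    set_id: int
    words: tuple[NonsenseWord, ...]

    @property
    def syllables(self) -> tuple[Syllable, ...]:
        seen: dict[Syllable, None] = {}
        for w in self.words:
            seen.setdefault(w.first)
            seen.setdefault(w.second)
        return tuple(seen)

    def __iter__(self):
        return iter(self.words)

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class VowelRealization:
    vowel: str
    stressed_ipa: str
    unstressed_ipa: str


# The printed word lists.  The published table lays the two sets out in
# side-by-side columns, so reading the rows left to right alternates
# set-1 and set-2 words.  This transcription is frozen here and guarded by
# validate_set(): it is the unique column assignment under which each set
# has 6 syllables, each used twice initially and twice finally, with
# disjoint inventories across sets.
_SET1_WORDS = (
    "puvo", "puga", "zipu", "gapu", "nake", "navo",
    "kena", "gazi", "ziga", "kezi", "vona", "voke",
)
_SET2_WORDS = (
    "tosu", "tomi", "jito", "sude", "deji", "delu",
    "jimi", "luto", "sulu", "miji", "lusu", "mide",
)


def build_training_sets() -> tuple[WordSet, WordSet]:
    """Return the two 12-word training sets.

    Both sets satisfy every structural invariant checked by
    :func:`validate_set`.
    """
    set1 = WordSet(1, tuple(NonsenseWord.from_text(t, 1) for t in _SET1_WORDS))
    set2 = WordSet(2, tuple(NonsenseWord.from_text(t, 2) for t in _SET2_WORDS))
    return set1, set2


def vowel_realization(vowel: str, stressed: bool) -> str:
    """IPA realization of an orthographic vowel under the given stress.

    Stressed syllables carry the full (long) vowel; unstressed syllables
    the reduced one (schwa for A/O/U, lax counterparts for E/I).
    """
    try:
        stressed_ipa, unstressed_ipa = VOWEL_TABLE[vowel]
    except KeyError:
        raise ValueError(f"unknown vowel {vowel!r}; expected one of {VOWELS}") from None
    return stressed_ipa if stressed else unstressed_ipa


def consonant_inventory(sets: Iterable[WordSet] | None = None) -> tuple[str, ...]:
    """Consonant onsets induced by the word lists (12 consonants in all)."""
    if sets is None:
        sets = build_training_sets()
    seen: dict[str, None] = {}
    for ws in sets:
        for w in ws.words:
            seen.setdefault(w.first.onset)
            seen.setdefault(w.second.onset)
    return tuple(seen)


def validate_set(ws: WordSet, other: WordSet | None = None) -> dict[str, bool]:
    """Check the structural invariants of a word set; never raises.

    Returns a mapping of check name -> pass/fail.  ``disjoint_from_other``
    is only present when a second set is supplied.  A set with every check
    passing is usable for trial scheduling.
    """
    report: dict[str, bool] = {}
    report["twelve_words"] = len(ws.words) == 12
    sylls = ws.syllables
    report["six_syllables"] = len(sylls) == 6

    first_counts = {s: 0 for s in sylls}
    second_counts = {s: 0 for s in sylls}
    for w in ws.words:
        first_counts[w.first] = first_counts.get(w.first, 0) + 1
        second_counts[w.second] = second_counts.get(w.second, 0) + 1
    report["usage_counts"] = all(
        first_counts.get(s, 0) == 2 and second_counts.get(s, 0) == 2 for s in sylls
    ) and len(ws.words) == 12
    report["no_repeated_syllable_within_word"] = all(w.first != w.second for w in ws.words)
    report["unique_words"] = len({w.text for w in ws.words}) == len(ws.words)
    report["consistent_set_id"] = all(w.set_id == ws.set_id for w in ws.words)

    if other is not None:
        report["disjoint_from_other"] = not (set(ws.syllables) & set(other.syllables))
    return report


def export_wordsets_csv(path: str | Path, sets: Iterable[WordSet] | None = None) -> None:
    """Write word sets as CSV (set_id, word, syllable1, syllable2)."""
    if sets is None:
        sets = build_training_sets()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["set_id", "word", "syllable1", "syllable2"])
        for ws in sets:
            for w in ws.words:
                writer.writerow([ws.set_id, w.text, w.first.text, w.second.text])


def import_wordsets_csv(path: str | Path) -> tuple[WordSet, ...]:
    """Read word sets written by :func:`export_wordsets_csv` (lossless)."""
    by_set: dict[int, list[NonsenseWord]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = int(row["set_id"])
            word = NonsenseWord.from_text(row["word"], sid)
            if word.first.text != row["syllable1"] or word.second.text != row["syllable2"]:
                raise ValueError(f"inconsistent row for word {row['word']!r}")
            by_set.setdefault(sid, []).append(word)
    return tuple(WordSet(sid, tuple(words)) for sid, words in sorted(by_set.items()))
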