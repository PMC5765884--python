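"""Letter-level parsing of disyllabic strings and extraction of sublexical stress cues.

A disyllabic letter string is split into two syllables around its two vowel
groups, with the intervocalic consonant cluster divided so that the second
syllable begins with the longest phonotactically legal onset (maximal-onset
principle).  From the syllabified form we read off the three sublexical cues
that readers are sensitive to when assigning stress to unfamiliar words:

* prefixation — does the string begin with a real English prefix (de-, mis-,
  pre-, re-)?
* second-vowel length — single short vowel letter vs. long vowel digraph
  (ai, ea, ee, oa, oo, ou);
* orthographic weight — letter counts of the two syllables and their signed
  difference (second minus first).

The *word ending* (all letters from the nucleus of the second syllable to the
end of the string, e.g. ``-ow`` in *follow*) is extracted as well, since
ending statistics act as covariates in the analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import (
    InvalidInputError,
    NotDisyllabicError,
    UnknownVowelError,
)

VOWEL_LETTERS = frozenset("aeiou")

_DEFAULT_SHORT_VOWELS = frozenset("aeou")
_DEFAULT_LONG_DIGRAPHS = frozenset({"ai", "ea", "ee", "oa", "oo", "ou"})
_DEFAULT_PREFIX_PAIRS = (("de", "do"), ("mis", "mes"), ("pre", "pra"), ("re", "ro"))
# All single consonants are legal onsets, plus the common English clusters.
# "sd" is deliberately absent, which forces splits such as mis.dut / mes.dut.
_DEFAULT_ONSET_CLUSTERS = (
    "bl", "br", "cl", "cr", "dr", "fl", "fr", "gl", "gr", "pl", "pr",
    "sc", "sk", "sl", "sm", "sn", "sp", "st", "str", "tr",
    "th", "sh", "ch", "wh", "ph",
)
_DEFAULT_STRESS_SUFFIXES = frozenset({"een", "ique", "oo"})
_DEFAULT_PLAIN_SUFFIXES = frozenset(
    {"er", "ow", "le", "ish", "ness", "ful", "less", "ing", "ed", "ly", "es", "en"}
)


@dataclass(frozen=True)
class LetterInventory:
    """Letter-level resources: vowel sets, legal onsets, affix lists.

    The defaults reproduce the stimulus-construction sets used throughout the
    experiments (short vowels a, e, o, u; long digraphs ai, ea, ee, oa, oo,
    ou; prefixes de-, mis-, pre-, re- with the matched non-prefix controls
    do-, mes-, pra-, ro-).  All fields are overridable via :meth:`from_file`
    so the same machinery applies to lexicon-wide analyses with richer affix
    lists.
    """

    short_vowels: frozenset[str] = _DEFAULT_SHORT_VOWELS
    long_vowel_digraphs: frozenset[str] = _DEFAULT_LONG_DIGRAPHS
    legal_onsets: frozenset[str] = field(default_factory=lambda: frozenset(
        set("bcdfghjklmnpqrstvwxz") | set(_DEFAULT_ONSET_CLUSTERS)
    ))
    prefix_pairs: tuple[tuple[str, str], ...] = _DEFAULT_PREFIX_PAIRS
    stress_taking_suffixes: frozenset[str] = _DEFAULT_STRESS_SUFFIXES
    plain_suffixes: frozenset[str] = _DEFAULT_PLAIN_SUFFIXES

    def __post_init__(self) -> None:
        consonants = set("bcdfghjklmnpqrstvwxyz") - set("aeiou")
        if self.short_vowels & consonants:
            raise ValueError("short_vowels overlap consonants")
        prefixes = [p for p, _ in self.prefix_pairs]
        if len(prefixes) != len(set(prefixes)):
            raise ValueError("duplicate prefix in prefix_pairs")
        if self.stress_taking_suffixes & self.plain_suffixes:
            raise ValueError("a suffix appears in both suffix sets")

    @property
    def prefixes(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.prefix_pairs)

    @property
    def prefix_controls(self) -> tuple[str, ...]:
        return tuple(c for _, c in self.prefix_pairs)

    @classmethod
    def from_file(cls, path) -> "LetterInventory":
        """Load an inventory from a YAML (or JSON, a YAML subset) config."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = {}
        for key in ("short_vowels", "long_vowel_digraphs", "legal_onsets",
                    "stress_taking_suffixes", "plain_suffixes"):
            if key in raw:
                kwargs[key] = frozenset(raw[key])
        if "prefix_pairs" in raw:
            kwargs["prefix_pairs"] = tuple((p, c) for p, c in raw["prefix_pairs"])
        return cls(**kwargs)


@dataclass(frozen=True)
class Syllabification:
    """A two-way split of a disyllabic string, with its two vowel groups."""

    syllable1: str
    syllable2: str
    vowel1: str
    vowel2: str
    used_y_as_vowel: bool = False

    @property
    def spelling(self) -> str:
        return self.syllable1 + self.syllable2


@dataclass(frozen=True)
class CueProfile:
    """The sublexical cue vector of one letter string."""

    spelling: str
    has_prefix: bool
    prefix_id: Optional[str]
    second_vowel_length: str  # "short" | "long"
    weight_s1: int
    weight_s2: int
    weight_diff: int
    ending: Optional[str]


def _is_vowel_at(s: str, i: int) -> bool:
    """y counts as a vowel only when neither neighbour is a vowel letter
    (vowel in *abyss*, consonant in *beyond*)."""
    ch = s[i]
    if ch in VOWEL_LETTERS:
        return True
    if ch != "y":
        return False
    left = s[i - 1] if i > 0 else ""
    right = s[i + 1] if i < len(s) - 1 else ""
    return left not in VOWEL_LETTERS and right not in VOWEL_LETTERS


def vowel_groups(spelling: str) -> list[tuple[int, int]]:
    """Return (start, end) index pairs of maximal vowel-letter runs."""
    groups = []
    i = 0
    n = len(spelling)
    while i < n:
        if _is_vowel_at(spelling, i):
            j = i
            while j < n and _is_vowel_at(spelling, j):
                j += 1
            groups.append((i, j))
            i = j
        else:
            i += 1
    return groups


def _check_spelling(spelling: str) -> None:
    if not spelling:
        raise InvalidInputError("empty letter string")
    if not spelling.isalpha() or not spelling.islower():
        raise InvalidInputError(f"not a lowercase alphabetic string: {spelling!r}")


def syllabify(spelling: str, inv: LetterInventory | None = None) -> Syllabification:
    """Split a disyllabic string so the second syllable takes the longest
    legal onset from the intervocalic consonant cluster.

    Raises :class:`NotDisyllabicError` unless the string contains exactly two
    vowel groups.
    """
    inv = inv or LetterInventory()
    _check_spelling(spelling)
    groups = vowel_groups(spelling)
    if len(groups) != 2:
        raise NotDisyllabicError(
            f"{spelling!r} has {len(groups)} vowel group(s); need exactly 2"
        )
    (s1, e1), (s2, e2) = groups
    cluster = spelling[e1:s2]
    onset_len = 0
    for k in range(len(cluster), 0, -1):
        if cluster[-k:] in inv.legal_onsets:
            onset_len = k
            break
    boundary = s2 - onset_len
    uses_y = "y" in spelling[s1:e1] or "y" in spelling[s2:e2]
    return Syllabification(
        syllable1=spelling[:boundary],
        syllable2=spelling[boundary:],
        vowel1=spelling[s1:e1],
        vowel2=spelling[s2:e2],
        used_y_as_vowel=uses_y,
    )


def detect_prefix(
    spelling: str, inv: LetterInventory | None = None
) -> tuple[bool, Optional[str]]:
    """Longest-match prefix detection; the remainder must itself carry a vowel."""
    inv = inv or LetterInventory()
    _check_spelling(spelling)
    best = None
    for prefix in inv.prefixes:
        if spelling.startswith(prefix) and (best is None or len(prefix) > len(best)):
            remainder = spelling[len(prefix):]
            if vowel_groups(remainder):
                best = prefix
    return (best is not None, best)


def classify_second_vowel(s: Syllabification, inv: LetterInventory | None = None) -> str:
    """Classify the second vowel group as ``"short"`` or ``"long"``."""
    inv = inv or LetterInventory()
    v = s.vowel2
    if v in inv.long_vowel_digraphs:
        return "long"
    if len(v) == 1:
        return "short"
    raise UnknownVowelError(f"vowel group {v!r} not in inventory")


def orthographic_weights(s: Syllabification) -> tuple[int, int, int]:
    """Letter counts of both syllables and their signed difference (s2 − s1)."""
    w1, w2 = len(s.syllable1), len(s.syllable2)
    return w1, w2, w2 - w1


def extract_ending(spelling: str, inv: LetterInventory | None = None) -> Optional[str]:
    """All final letters from the nucleus of the second syllable onwards
    (``-ow`` in *follow*, ``-ark`` in *embark*).  ``None`` when the string has
    no second vowel group (syllabic-consonant words have no word ending)."""
    _check_spelling(spelling)
    groups = vowel_groups(spelling)
    if len(groups) < 2:
        return None
    start = groups[1][0]
    return spelling[start:]


def cue_profile(spelling: str, inv: LetterInventory | None = None) -> CueProfile:
    """Bundle the four cue extractors into one profile for a disyllabic string."""
    inv = inv or LetterInventory()
    s = syllabify(spelling, inv)
    has_prefix, prefix_id = detect_prefix(spelling, inv)
    length = classify_second_vowel(s, inv)
    w1, w2, diff = orthographic_weights(s)
    return CueProfile(
        spelling=spelling,
        has_prefix=has_prefix,
        prefix_id=prefix_id,
        second_vowel_length=length,
        weight_s1=w1,
        weight_s2=w2,
        weight_diff=diff,
        ending=extract_ending(spelling, inv),
    )
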