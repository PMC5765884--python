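"""Corpus container and the distributional statistics the models consume.

The lexicon emulates a disyllabic corpus in which every row carries a
spelling, a period-syllabified spelling, the stressed syllable (1 or 2) and a
word class.  From it we derive:

* orthographic neighbourhood covariates — Coltheart's N (same-length
  one-substitution neighbours) and OLD20 (mean Levenshtein distance to the 20
  nearest spellings);
* mean bigram type frequency;
* word-ending statistics — how many disyllables share a target's ending and
  what fraction of those take second-syllable stress;
* the base rate of second-syllable stress and the cue-conditional likelihood
  tables that feed the Bayesian stress model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional, Sequence

import edlib
import pandas as pd

from .errors import InvalidInputError, StressCueError
from .orthography import CueProfile, LetterInventory, cue_profile, extract_ending

#: weight_diff buckets for the Bayesian weight cue: negative, zero, positive
WEIGHT_BUCKETS = ("neg", "zero", "pos")


def weight_bucket(weight_diff: int) -> str:
    if weight_diff < 0:
        return "neg"
    if weight_diff > 0:
        return "pos"
    return "zero"


@dataclass(frozen=True)
class LexEntry:
    """One corpus word."""

    spelling: str
    syllabified: str
    stress: int
    word_class: str = "other"
    frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.syllabified.replace(".", "") != self.spelling:
            raise InvalidInputError(
                f"syllabified form {self.syllabified!r} does not match "
                f"spelling {self.spelling!r}"
            )
        if self.syllabified.count(".") != 1:
            raise InvalidInputError(f"{self.syllabified!r} is not disyllabic")
        if self.stress not in (1, 2):
            raise InvalidInputError(f"stress must be 1 or 2, got {self.stress}")


@dataclass
class Lexicon:
    """An ordered collection of disyllabic entries, plus optional monosyllables."""

    entries: list[LexEntry]
    monosyllables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if e.spelling in seen:
                raise InvalidInputError(f"duplicate spelling {e.spelling!r}")
            seen.add(e.spelling)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @cached_property
    def spellings(self) -> list[str]:
        return [e.spelling for e in self.entries]

    @cached_property
    def spelling_set(self) -> frozenset[str]:
        return frozenset(self.spellings)

    @cached_property
    def monosyllable_set(self) -> frozenset[str]:
        return frozenset(self.monosyllables)

    @cached_property
    def _bigram_type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for w in self.spellings:
            for bg in {w[i : i + 2] for i in range(len(w) - 1)}:
                counts[bg] = counts.get(bg, 0) + 1
        return counts

    @classmethod
    def from_csv(
        cls,
        path,
        monosyllables: Optional[Iterable[str]] = None,
        sep: Optional[str] = None,
    ) -> "Lexicon":
        """Read a lexicon from a CSV/TSV file with columns
        ``spelling, syllabified, stress, word_class[, frequency]``.

        Invariant violations are reported with the offending line number.
        """
        df = pd.read_csv(path, sep=sep, engine="python")
        required = {"spelling", "syllabified", "stress"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"missing columns: {sorted(missing)}")
        entries = []
        for idx, row in df.iterrows():
            try:
                entries.append(
                    LexEntry(
                        spelling=str(row["spelling"]),
                        syllabified=str(row["syllabified"]),
                        stress=int(row["stress"]),
                        word_class=str(row.get("word_class", "other")),
                        frequency=(
                            float(row["frequency"])
                            if "frequency" in df.columns and pd.notna(row["frequency"])
                            else None
                        ),
                    )
                )
            except (InvalidInputError, ValueError) as exc:
                # +2: header line plus 1-based numbering
                raise InvalidInputError(f"line {idx + 2}: {exc}") from exc
        return cls(entries=entries, monosyllables=list(monosyllables or []))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "spelling": [e.spelling for e in self.entries],
                "syllabified": [e.syllabified for e in self.entries],
                "stress": [e.stress for e in self.entries],
                "word_class": [e.word_class for e in self.entries],
                "frequency": [e.frequency for e in self.entries],
            }
        ).to_csv(path, index=False)


def coltheart_n(target: str, lex: Lexicon) -> int:
    """Number of same-length lexicon spellings differing from the target by
    exactly one substituted letter (the target itself excluded)."""
    if not target:
        raise InvalidInputError("empty target")
    n = 0
    L = len(target)
    for w in lex.spellings:
        if len(w) != L or w == target:
            continue
        diffs = 0
        for a, b in zip(target, w):
            if a != b:
                diffs += 1
                if diffs > 1:
                    break
        if diffs == 1:
            n += 1
    return n


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute)."""
    return edlib.align(a, b)["editDistance"]


def old20(target: str, lex: Lexicon, k: int = 20) -> float:
    """Mean edit distance from the target to its *k* nearest lexicon
    spellings, self excluded.  Ties at the rank boundary are resolved by a
    stable sort on (distance, spelling)."""
    if not len(lex):
        raise StressCueError("empty lexicon")
    pairs = sorted(
        (levenshtein(target, w), w) for w in lex.spellings if w != target
    )
    if len(pairs) < k:
        warnings.warn(
            f"lexicon has only {len(pairs)} comparison spellings (< {k}); "
            "averaging over all of them",
            stacklevel=2,
        )
    nearest = pairs[:k]
    return sum(d for d, _ in nearest) / len(nearest)


def mean_bigram_frequency(target: str, lex: Lexicon) -> float:
    """Mean, over the target's adjacent letter pairs, of the number of
    lexicon types containing that pair anywhere (position-independent)."""
    if len(target) < 2:
        raise InvalidInputError("target must have at least two letters")
    counts = lex._bigram_type_counts
    bigrams = [target[i : i + 2] for i in range(len(target) - 1)]
    return sum(counts.get(bg, 0) for bg in bigrams) / len(bigrams)


@dataclass(frozen=True)
class EndingStats:
    """Ending frequency and ending-to-second-syllable-stress proportion."""

    ending: Optional[str]
    frequency: int
    stress2_proportion: float
    defined: bool  # the target has a word ending at all
    attested: bool  # at least one lexicon entry shares it


def ending_stats(
    target: str, lex: Lexicon, inv: LetterInventory | None = None
) -> EndingStats:
    """Count lexicon entries sharing the target's word ending and the
    fraction of those stressed on the second syllable."""
    inv = inv or LetterInventory()
    ending = extract_ending(target, inv)
    if ending is None:
        return EndingStats(None, 0, 0.0, defined=False, attested=False)
    total = 0
    stress2 = 0
    for e in lex.entries:
        if extract_ending(e.spelling, inv) == ending:
            total += 1
            if e.stress == 2:
                stress2 += 1
    if total == 0:
        return EndingStats(ending, 0, 0.0, defined=True, attested=False)
    return EndingStats(ending, total, stress2 / total, defined=True, attested=True)


def stress_prior(lex: Lexicon) -> float:
    """Fraction of corpus entries stressed on the second syllable."""
    if not len(lex):
        raise StressCueError("empty lexicon")
    return sum(e.stress == 2 for e in lex.entries) / len(lex)


def cue_states(profile: CueProfile) -> dict[str, str]:
    """Map a cue profile onto the discrete cue states used by the Bayesian model."""
    return {
        "prefix": "present" if profile.has_prefix else "absent",
        "vowel_length": profile.second_vowel_length,
        "weight": weight_bucket(profile.weight_diff),
    }


CUE_STATE_SPACE: dict[str, tuple[str, ...]] = {
    "prefix": ("present", "absent"),
    "vowel_length": ("long", "short"),
    "weight": WEIGHT_BUCKETS,
}

#: which state of each cue counts as "cue present" for the sequential update
CUE_PRESENT_STATE: dict[str, str] = {
    "prefix": "present",
    "vowel_length": "long",
    "weight": "pos",
}


def cue_likelihoods(lex: Lexicon, inv: LetterInventory | None = None):
    """Estimate the prior and the per-cue conditional likelihood tables
    P(cue-state | stress class) from the corpus, with add-one smoothing.

    Returns a :class:`~stresscue.models.bayes.BayesParams`.  Entries whose cue
    profile cannot be computed (e.g. unknown vowel digraphs) are skipped with
    a warning.
    """
    from .models.bayes import BayesParams  # local import avoids a module cycle

    inv = inv or LetterInventory()
    if not len(lex):
        raise StressCueError("empty lexicon")
    counts = {
        cue: {state: [0, 0] for state in states}  # [stress1, stress2]
        for cue, states in CUE_STATE_SPACE.items()
    }
    n_by_class = [0, 0]
    skipped = []
    for e in lex.entries:
        try:
            states = cue_states(cue_profile(e.spelling, inv))
        except StressCueError:
            skipped.append(e.spelling)
            continue
        cls_idx = e.stress - 1
        n_by_class[cls_idx] += 1
        for cue, state in states.items():
            counts[cue][state][cls_idx] += 1
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} entries without computable cue profiles",
            stacklevel=2,
        )
    total = sum(n_by_class)
    if total == 0:
        raise StressCueError("no entries with computable cue profiles")
    tables: dict[str, dict[str, tuple[float, float]]] = {}
    for cue, states in CUE_STATE_SPACE.items():
        k = len(states)
        tables[cue] = {}
        for state in states:
            c1, c2 = counts[cue][state]
            p_s1 = (c1 + 1) / (n_by_class[0] + k)
            p_s2 = (c2 + 1) / (n_by_class[1] + k)
            tables[cue][state] = (p_s2, p_s1)
    return BayesParams(
        prior_s2=n_by_class[1] / total,
        tables=tables,
        cue_order=("prefix", "vowel_length", "weight"),
    )
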