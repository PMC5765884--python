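"""The affix-rule stress algorithm.

A deterministic, all-or-none rule cascade for disyllables: identifying a
prefix assigns second-syllable stress; otherwise identifying a suffix assigns
first-syllable stress, except for a small set of stress-taking suffixes
(-een, -ique, -oo) which assign second-syllable stress; with no affix at all
the English default of first-syllable stress applies.
"""

from __future__ import annotations

from ..errors import NotDisyllabicError
from ..orthography import LetterInventory, detect_prefix, syllabify


def _detect_suffix(spelling: str, inv: LetterInventory) -> tuple[str, str] | None:
    """Longest suffix match over both suffix sets; returns (suffix, kind)."""
    best: tuple[str, str] | None = None
    for suffix in inv.stress_taking_suffixes:
        if spelling.endswith(suffix) and len(suffix) < len(spelling):
            if best is None or len(suffix) > len(best[0]):
                best = (suffix, "stress_taking")
    for suffix in inv.plain_suffixes:
        if spelling.endswith(suffix) and len(suffix) < len(spelling):
            if best is None or len(suffix) > len(best[0]):
                best = (suffix, "plain")
    return best


def rc00_stress(spelling: str, inv: LetterInventory | None = None) -> int:
    """Apply the rule cascade to a disyllabic letter string.

    Raises :class:`NotDisyllabicError` for strings without exactly two vowel
    groups (the rules are defined for disyllables only).
    """
    inv = inv or LetterInventory()
    syllabify(spelling, inv)  # raises NotDisyllabicError when not disyllabic
    has_prefix, _ = detect_prefix(spelling, inv)
    if has_prefix:
        return 2
    suffix = _detect_suffix(spelling, inv)
    if suffix is not None:
        return 2 if suffix[1] == "stress_taking" else 1
    return 1
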