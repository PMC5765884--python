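import pytest

from stresscue.lexicon import LexEntry, Lexicon
from stresscue.orthography import LetterInventory
from stresscue.synthetic import LexiconConfig, generate_lexicon


@pytest.fixture(scope="session")
def inv() -> LetterInventory:
    return LetterInventory()


@pytest.fixture(scope="session")
def toy_lexicon() -> Lexicon:
    """Tiny hand-built lexicon for exact counting checks."""
    rows = [
        ("follow", "fol.low", 1, "verb"),
        ("hollow", "hol.low", 1, "other"),
        ("allow", "al.low", 2, "verb"),
        ("prelel", "pre.lel", 2, "noun"),
        ("embark", "em.bark", 2, "verb"),
        ("erupt", "e.rupt", 2, "verb"),
        ("camel", "ca.mel", 1, "noun"),
        ("canal", "ca.nal", 2, "noun"),
    ]
    return Lexicon(
        entries=[LexEntry(s, syl, st, wc) for s, syl, st, wc in rows],
        monosyllables=["dut", "mark", "red", "press"],
    )


@pytest.fixture(scope="session")
def synth_lexicon() -> Lexicon:
    """Moderate synthetic corpus shared by statistics and model tests."""
    cfg = LexiconConfig(n_disyllables=2000, n_monosyllables=300, seed=20)
    return generate_lexicon(cfg)


# ---------------------------------------------------------------------------
# lexicon with cues conditionally independent given stress, for the
# joint-count oracle of the Bayesian model
# ---------------------------------------------------------------------------

#: inventory with consonant-final first units of lengths 3 and 4, so that
#: every weight bucket is reachable for both vowel lengths
CI_INVENTORY = LetterInventory(
    prefix_pairs=(("ben", "bon"), ("bend", "bond")),
)

_CI_ONSET1 = tuple("bdfglkmnpstv")
_CI_ONSET2 = ("st", "sp", "sk", "sl", "sm", "sn", "bl", "cl", "fl", "gl", "pl")
_CI_CODA1 = tuple("bdfgklmnpstv")
_CI_CODA2 = ("st", "nd", "nt", "lt", "sk", "mp", "ft", "lk")
_CI_SHORT = ("a", "e", "o", "u")
_CI_LONG = ("ai", "ea", "ee", "oa", "oo", "ou")

CI_TRUE = {
    "p_s2": 0.27,
    "p_prefix": {1: 0.20, 2: 0.55},
    "p_long": {1: 0.25, 2: 0.50},
    "p_wpos": {1: 0.35, 2: 0.60},
}


def make_ci_lexicon(n: int, seed: int) -> Lexicon:
    """Sample stress first, then the three cue states independently given the
    stress class, then synthesise a spelling realising exactly that cue
    combination.  By construction the cues are conditionally independent
    given stress, so staged naive-Bayes updating matches joint counting."""
    import numpy as np

    from stresscue.orthography import syllabify

    rng = np.random.default_rng(seed)
    inv = CI_INVENTORY
    entries, seen = [], set()
    while len(entries) < n:
        stress = 2 if rng.random() < CI_TRUE["p_s2"] else 1
        has_prefix = rng.random() < CI_TRUE["p_prefix"][stress]
        is_long = rng.random() < CI_TRUE["p_long"][stress]
        wpos = rng.random() < CI_TRUE["p_wpos"][stress]
        units = inv.prefixes if has_prefix else inv.prefix_controls
        unit = units[int(rng.integers(len(units)))]
        vowel = (_CI_LONG if is_long else _CI_SHORT)[
            int(rng.integers(6 if is_long else 4))
        ]
        v = len(vowel)
        candidates = [len(unit) + 1, len(unit) + 2] if wpos else [len(unit)]
        feasible = [L for L in candidates if v + 1 <= L <= v + 4]
        s2len = feasible[int(rng.integers(len(feasible)))]
        budget = s2len - v
        options = [
            (o, budget - o) for o in (1, 2) if 0 <= budget - o <= 2
        ]
        o_len, c_len = options[int(rng.integers(len(options)))]
        onset = (_CI_ONSET1 if o_len == 1 else _CI_ONSET2)[
            int(rng.integers(len(_CI_ONSET1 if o_len == 1 else _CI_ONSET2)))
        ]
        coda = ("" if c_len == 0 else
                (_CI_CODA1 if c_len == 1 else _CI_CODA2)[
                    int(rng.integers(len(_CI_CODA1 if c_len == 1 else _CI_CODA2)))
                ])
        w = unit + onset + vowel + coda
        if w in seen:
            continue
        s = syllabify(w, inv)
        if s.syllable1 != unit:  # keep the unit aligned with the boundary
            continue
        seen.add(w)
        entries.append(LexEntry(w, f"{s.syllable1}.{s.syllable2}", stress))
    return Lexicon(entries)
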