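"""Corpus covariates: neighbourhoods, bigram frequency, endings, priors."""

import numpy as np
import pytest

from stresscue.errors import InvalidInputError, StressCueError
from stresscue.lexicon import (
    LexEntry,
    Lexicon,
    coltheart_n,
    cue_likelihoods,
    ending_stats,
    mean_bigram_frequency,
    old20,
    stress_prior,
)


def _entry(spelling, stress=1, word_class="other"):
    s = spelling
    return LexEntry(s, s[:2] + "." + s[2:], stress, word_class)


def _dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming oracle for the edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _random_words(rng, n, lengths=(4, 5, 6, 7)):
    letters = "abdelmnoprstu"
    out = []
    while len(out) < n:
        L = int(rng.choice(lengths))
        w = "".join(rng.choice(list(letters), size=L))
        if w not in out:
            out.append(w)
    return out


class TestColtheartN:
    def test_single_substitution_neighbour(self):
        lex = Lexicon([_entry("prelel")])
        assert coltheart_n("pralel", lex) >= 1

    def test_no_equal_length_words(self):
        lex = Lexicon([_entry("prelel")])
        assert coltheart_n("embarks", lex) == 0

    def test_self_excluded(self):
        lex = Lexicon([_entry("pralel"), _entry("prelel")])
        assert coltheart_n("pralel", lex) == 1

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(3)
        words = _random_words(rng, 200)
        lex = Lexicon([_entry(w) for w in words])
        for target in words[:25]:
            expected = sum(
                1
                for w in words
                if w != target
                and len(w) == len(target)
                and sum(a != b for a, b in zip(w, target)) == 1
            )
            assert coltheart_n(target, lex) == expected


class TestOld20:
    def test_twenty_neighbours_at_distance_one(self):
        base = "salet"
        variants = []
        for i in range(len(base)):
            for ch in "bcdfgjkm":
                w = base[:i] + ch + base[i + 1:]
                if w != base and w not in variants:
                    variants.append(w)
        lex = Lexicon([_entry(w) for w in variants[:20]])
        assert old20(base, lex) == 1.0

    def test_self_excluded(self):
        lex = Lexicon([_entry("salet")] + [_entry(w) for w in
                                           ("balet", "calet", "dalet")])
        with pytest.warns(UserWarning):
            val = old20("salet", lex)
        assert val == 1.0  # the identical entry contributes nothing

    def test_empty_lexicon_errors(self):
        with pytest.raises(StressCueError):
            old20("salet", Lexicon([]))

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(11)
        words = _random_words(rng, 60)
        lex = Lexicon([_entry(w) for w in words])
        for target in ["salet", words[5]]:
            dists = sorted(
                (_dp_levenshtein(target, w), w) for w in words if w != target
            )
            expected = np.mean([d for d, _ in dists[:20]])
            assert old20(target, lex) == pytest.approx(expected)


class TestBigramFrequency:
    def test_absent_bigrams(self):
        lex = Lexicon([_entry("sotul")])
        assert mean_bigram_frequency("gagag", lex) == 0.0

    def test_single_entry_equal_to_target(self):
        lex = Lexicon([_entry("pralel")])
        assert mean_bigram_frequency("pralel", lex) == 1.0

    def test_too_short_errors(self):
        with pytest.raises(InvalidInputError):
            mean_bigram_frequency("a", Lexicon([_entry("pralel")]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        words = _random_words(rng, 100)
        lex = Lexicon([_entry(w) for w in words])
        for target in words[:10]:
            bigrams = [target[i:i + 2] for i in range(len(target) - 1)]
            expected = np.mean([sum(bg in w for w in words) for bg in bigrams])
            assert mean_bigram_frequency(target, lex) == pytest.approx(expected)


class TestEndingStats:
    def test_toy_counts(self, toy_lexicon, inv):
        res = ending_stats("sorrow", toy_lexicon, inv)
        assert res.ending == "ow"
        assert res.frequency == 3  # follow, hollow, allow
        assert res.stress2_proportion == pytest.approx(1 / 3)

    def test_absent_ending_flagged(self, toy_lexicon, inv):
        res = ending_stats("sotuss", toy_lexicon, inv)
        assert res.frequency == 0 and not res.attested

    def test_all_sharers_second_stress(self, inv):
        lex = Lexicon([_entry("embark", 2), _entry("remark", 2)])
        res = ending_stats("debark", lex, inv)
        assert res.stress2_proportion == 1.0

    def test_undefined_ending(self, toy_lexicon, inv):
        res = ending_stats("spasm", toy_lexicon, inv)
        assert not res.defined


class TestStressPrior:
    def test_printed_rate_on_toy_split(self):
        spellings = [
            "sat" + chr(97 + i // 10) + chr(97 + i % 10) for i in range(100)
        ]
        lex = Lexicon([_entry(w, 2 if i < 27 else 1)
                       for i, w in enumerate(spellings)])
        assert stress_prior(lex) == pytest.approx(0.27)

    def test_all_first_stress(self):
        lex = Lexicon([_entry("pralel", 1), _entry("mesdut", 1)])
        assert stress_prior(lex) == 0.0

    def test_empty_errors(self):
        with pytest.raises(StressCueError):
            stress_prior(Lexicon([]))

    def test_random_equals_direct_count(self, synth_lexicon):
        direct = np.mean([e.stress == 2 for e in synth_lexicon.entries])
        assert stress_prior(synth_lexicon) == pytest.approx(direct)


class TestCueLikelihoods:
    def test_prefix_perfectly_predicts(self, inv):
        entries = [
            LexEntry("prebak", "pre.bak", 2), LexEntry("relut", "re.lut", 2),
            LexEntry("misdut", "mis.dut", 2), LexEntry("debak", "de.bak", 2),
            LexEntry("prabak", "pra.bak", 1), LexEntry("rolut", "ro.lut", 1),
            LexEntry("mesdut", "mes.dut", 1), LexEntry("dobak", "do.bak", 1),
        ]
        params = cue_likelihoods(Lexicon(entries), inv)
        p2_present, p1_present = params.tables["prefix"]["present"]
        assert 0.5 < p2_present < 1.0  # smoothed below 1
        assert 0.0 < p1_present < 0.5
        assert p2_present > p1_present

    def test_conditionals_sum_to_one(self, synth_lexicon, inv):
        params = cue_likelihoods(synth_lexicon, inv)
        for cue, table in params.tables.items():
            s2 = sum(p2 for p2, _ in table.values())
            s1 = sum(p1 for _, p1 in table.values())
            assert s2 == pytest.approx(1.0)
            assert s1 == pytest.approx(1.0)

    def test_empty_cells_smoothed_nonzero(self, inv):
        # no long-vowel words at all: that cell must still get mass
        entries = [LexEntry("pralel", "pra.lel", 1),
                   LexEntry("mesdut", "mes.dut", 2)]
        params = cue_likelihoods(Lexicon(entries), inv)
        p2_long, p1_long = params.tables["vowel_length"]["long"]
        assert p2_long > 0 and p1_long > 0

    def test_independent_cue_has_equal_conditionals(self, inv):
        # vowel length balanced within each stress class by construction
        entries = []
        for i, (unit, onset) in enumerate(
            [("pra", "b"), ("mes", "d"), ("ro", "g"), ("do", "l"),
             ("pra", "t"), ("mes", "n"), ("ro", "s"), ("do", "m")]
        ):
            for j, vowel in enumerate(("e", "ea")):
                w = unit + onset + vowel + "p"
                stress = 1 if i < 4 else 2
                entries.append(LexEntry(w, unit + "." + w[len(unit):], stress))
        params = cue_likelihoods(Lexicon(entries), inv)
        p2_long, p1_long = params.tables["vowel_length"]["long"]
        assert p2_long == pytest.approx(p1_long)
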