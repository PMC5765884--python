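"""Matching transforms, item validation, factorial sets, blocking, lists."""

import numpy as np
import pytest

from stresscue.errors import GenerationError, TransformNotApplicableError
from stresscue.lexicon import Lexicon
from stresscue.orthography import cue_profile, syllabify
from stresscue.stimuli import (
    COMBOS,
    MAX_CONTEXT_RUN,
    MIN_PAIR_DISTANCE,
    DesignSpec,
    apply_transform,
    assign_blocks,
    generate_exp4_lists,
    generate_factorial_set,
    validate_item,
)


@pytest.fixture(scope="module")
def empty_lex():
    return Lexicon([])


class TestTransforms:
    @pytest.mark.parametrize(
        "spelling, transform, kwargs, expected",
        [
            ("prelel", "prefix_swap", {}, "pralel"),
            ("pralel", "prefix_swap", {}, "prelel"),
            ("prelel", "vowel_lengthen", {"choice": "ea"}, "preleal"),
            ("pralel", "vowel_lengthen", {"choice": "ea"}, "praleal"),
            ("prelel", "add_weight", {}, "prelell"),
            ("preleal", "vowel_shorten", {}, "prelel"),
        ],
    )
    def test_examples(self, spelling, transform, kwargs, expected, inv):
        assert apply_transform(spelling, transform, inv, **kwargs) == expected

    def test_prefix_swap_self_inverse(self, inv):
        for w in ("prelel", "pralel", "misdut", "mesdut", "debak", "rolut"):
            assert apply_transform(
                apply_transform(w, "prefix_swap", inv), "prefix_swap", inv
            ) == w

    def test_lengthen_shorten_identity(self, inv):
        rng = np.random.default_rng(0)
        for w in ("prelel", "misdut", "dobak", "rosud"):
            long_w = apply_transform(w, "vowel_lengthen", inv, rng=rng)
            assert apply_transform(long_w, "vowel_shorten", inv) == w

    def test_not_applicable(self, inv):
        with pytest.raises(TransformNotApplicableError):
            apply_transform("praleal", "vowel_lengthen", inv)  # already long
        with pytest.raises(TransformNotApplicableError):
            apply_transform("banana", "prefix_swap", inv)


class TestValidateItem:
    def test_standard_item_valid(self, toy_lexicon, inv):
        valid, reasons = validate_item("pralel", toy_lexicon, inv)
        assert valid, reasons

    def test_monosyllable_syllable_invalid(self, toy_lexicon, inv):
        valid, reasons = validate_item("mesdut", toy_lexicon, inv)  # 'dut' listed
        assert not valid
        assert any("monosyllabic" in r for r in reasons)

    def test_length_bounds(self, toy_lexicon, inv):
        valid, reasons = validate_item("dodo", toy_lexicon, inv)
        assert not valid and any("length" in r for r in reasons)
        valid, _ = validate_item("dobak", toy_lexicon, inv, design_id="exp3")
        assert not valid  # exp3-style items must be 6-7 letters

    def test_real_word_invalid(self, toy_lexicon, inv):
        valid, reasons = validate_item("prelel", toy_lexicon, inv)
        assert not valid and any("real word" in r for r in reasons)


class TestFactorialGeneration:
    @pytest.mark.parametrize("design", ["exp1", "exp2", "exp3"])
    def test_cell_counts(self, design, empty_lex, inv):
        sset = generate_factorial_set(DesignSpec(design, 20, seed=2), empty_lex, inv)
        assert len(sset) == 80
        for cell in sset.design.cells:
            assert len(sset.spellings(cell)) == 20

    def test_small_set_structure(self, empty_lex, inv):
        sset = generate_factorial_set(DesignSpec("exp1", 2, seed=0), empty_lex, inv)
        assert len(sset) == 8
        groups = {it.match_group for it in sset.items}
        assert groups == {0, 1}

    def test_determinism(self, empty_lex, inv):
        a = generate_factorial_set(DesignSpec("exp1", 5, seed=9), empty_lex, inv)
        b = generate_factorial_set(DesignSpec("exp1", 5, seed=9), empty_lex, inv)
        assert a.spellings() == b.spellings()

    def test_all_items_validate(self, toy_lexicon, inv):
        sset = generate_factorial_set(DesignSpec("exp2", 10, seed=4),
                                      toy_lexicon, inv)
        for it in sset.items:
            valid, reasons = validate_item(it.spelling, toy_lexicon, inv, "exp2")
            assert valid, (it.spelling, reasons)

    def test_match_group_skeleton_shared(self, empty_lex, inv):
        """Outside the transformed unit, group members share their
        consonant skeleton."""
        sset = generate_factorial_set(DesignSpec("exp1", 10, seed=5),
                                      empty_lex, inv)
        by_group = {}
        for it in sset.items:
            by_group.setdefault(it.match_group, []).append(it.spelling)
        for spellings in by_group.values():
            skeletons = set()
            for w in spellings:
                s = syllabify(w, inv)
                cons = "".join(c for c in s.syllable2 if c not in "aeiou")
                skeletons.add(cons)
            assert len(skeletons) == 1

    def test_cells_comparable_on_coltheart_n(self, synth_lexicon, inv):
        from stresscue.lexicon import coltheart_n

        sset = generate_factorial_set(DesignSpec("exp1", 10, seed=6),
                                      synth_lexicon, inv, match_neighborhood=1)
        by_group = {}
        for it in sset.items:
            by_group.setdefault(it.match_group, []).append(it.spelling)
        for spellings in by_group.values():
            ns = [coltheart_n(w, synth_lexicon) for w in spellings]
            assert max(ns) - min(ns) <= 1
        means = {
            cell: np.mean([coltheart_n(w, synth_lexicon)
                           for w in sset.spellings(cell)])
            for cell in sset.design.cells
        }
        vals = list(means.values())
        assert max(vals) - min(vals) <= 1.0, means


class TestBlocking:
    def test_balanced_blocks(self, empty_lex, inv):
        sset = generate_factorial_set(DesignSpec("exp1", 20, seed=2), empty_lex, inv)
        blocked = assign_blocks(sset, 4, seed=2)
        for b in range(4):
            block_items = [it for it in blocked.items if it.block == b]
            assert len(block_items) == 20
            for cell in sset.design.cells:
                assert sum(it.cell == cell for it in block_items) == 5

    def test_match_groups_separated(self, empty_lex, inv):
        sset = generate_factorial_set(DesignSpec("exp1", 8, seed=3), empty_lex, inv)
        blocked = assign_blocks(sset, 4, seed=3)
        by_group = {}
        for it in blocked.items:
            by_group.setdefault(it.match_group, set()).add(it.block)
        for blocks in by_group.values():
            assert len(blocks) == 4

    def test_infeasible_blocking(self, empty_lex, inv):
        sset = generate_factorial_set(DesignSpec("exp1", 4, seed=3), empty_lex, inv)
        with pytest.raises(GenerationError):
            assign_blocks(sset, 2, seed=0)


@pytest.fixture(scope="module")
def lists(inv):
    lex = Lexicon([])
    sset = generate_factorial_set(DesignSpec("exp4", 40, seed=3), lex, inv)
    return generate_exp4_lists(sset.subset("cued"), sset.subset("noncued"),
                               seed=3)


class TestExp4Lists:
    def test_eighty_trials_per_list(self, lists):
        assert [len(l.trials) for l in lists] == [80, 80, 80, 80]

    def test_each_item_meets_all_contexts(self, lists):
        seen = {}
        for ca in lists:
            for t in ca.trials:
                seen.setdefault(t["spelling"], set()).add(
                    (t["syntactic"], t["rhythmic"])
                )
        for combos in seen.values():
            assert combos == set(COMBOS)

    def test_pair_spacing(self, lists):
        for ca in lists:
            pos = {}
            for t in ca.trials:
                pos.setdefault(t["match_group"], []).append(t["trial_index"])
            for a, b in pos.values():
                assert abs(a - b) >= MIN_PAIR_DISTANCE

    def test_context_run_limits(self, lists):
        for ca in lists:
            for axis in ("syntactic", "rhythmic"):
                run, prev = 0, None
                for t in ca.trials:
                    run = run + 1 if t[axis] == prev else 1
                    prev = t[axis]
                    assert run <= MAX_CONTEXT_RUN

    def test_condition_positions_fixed_across_lists(self, lists):
        signatures = [
            [(t["cue_status"], t["syntactic"], t["rhythmic"]) for t in ca.trials]
            for ca in lists
        ]
        assert all(sig == signatures[0] for sig in signatures[1:])

    def test_mismatched_sets_error(self, inv):
        lex = Lexicon([])
        a = generate_factorial_set(DesignSpec("exp4", 8, seed=1), lex, inv)
        b = generate_factorial_set(DesignSpec("exp4", 4, seed=2), lex, inv)
        with pytest.raises(GenerationError):
            generate_exp4_lists(a.subset("cued"), b.subset("noncued"), seed=0)
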