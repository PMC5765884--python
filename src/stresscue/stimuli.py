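"""Factorial nonword stimulus generation with pairwise matching.

Every stimulus set is built from *match-groups*: a base non-prefixed,
short-vowel skeleton (control unit + C V C second syllable, e.g. *pralel*)
from which the other cells are derived by minimal transforms —

* ``prefix_swap``   pralel ↔ prelel   (pra↔pre, mes↔mis, do↔de, ro↔re)
* ``vowel_lengthen``  prelel → preleal  (a→ai, e→ea/ee, o→oa, u→oo/ou)
* ``vowel_shorten``   the exact inverse
* ``add_weight``    prelel → prelell  (a digraph ph/sh/th or doubling
  ll/ss/ng added to the second syllable)

so that all members of a group share their consonant skeleton outside the
manipulated unit.  Designs:

* ``exp1`` prefixation × second-vowel length (5–7 letters)
* ``exp2`` prefixation × orthographic weight, short vowels only
* ``exp3`` prefixation × vowel length with second-syllable letter count
  held at four (6–7 letters)
* ``exp4`` cued (prefix + long vowel + heavier second syllable) vs.
  non-cued items, for sentence-context simulation.

Items are validated (disyllabic, legal intervocalic split aligned with the
prefix/control unit, no syllable equal to a listed monosyllable, not a real
word), divided into blocks so that conditions are balanced and matched items
never share a block, and — for the sentence experiment — arranged into four
pseudorandomised lists that rotate each item through every syntactic ×
rhythmic context combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError, TransformNotApplicableError
from .lexicon import Lexicon
from .orthography import LetterInventory, syllabify, vowel_groups

#: lengthening alternatives for each short vowel
LENGTHEN_MAP: dict[str, tuple[str, ...]] = {
    "a": ("ai",),
    "e": ("ea", "ee"),
    "o": ("oa",),
    "u": ("oo", "ou"),
}
SHORTEN_MAP: dict[str, str] = {
    long_v: short_v for short_v, longs in LENGTHEN_MAP.items() for long_v in longs
}

CELLS: dict[str, tuple[str, ...]] = {
    "exp1": ("nonprefixed_short", "prefixed_short",
             "nonprefixed_long", "prefixed_long"),
    "exp2": ("nonprefixed_light", "prefixed_light",
             "nonprefixed_heavy", "prefixed_heavy"),
    "exp3": ("nonprefixed_short", "prefixed_short",
             "nonprefixed_long", "prefixed_long"),
    "exp4": ("noncued", "cued"),
}

LENGTH_RANGE: dict[str, tuple[int, int]] = {
    "exp1": (5, 7), "exp2": (5, 7), "exp3": (6, 7), "exp4": (5, 7),
}

#: consonants used for sampling second-syllable onsets and codas
CONSONANT_POOL = "bdfglkmnprstv"


@dataclass(frozen=True)
class DesignSpec:
    design_id: str
    n_per_cell: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design_id not in CELLS:
            raise ValueError(f"unknown design {self.design_id!r}")
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")

    @property
    def cells(self) -> tuple[str, ...]:
        return CELLS[self.design_id]


@dataclass(frozen=True)
class StimulusItem:
    spelling: str
    cell: str
    match_group: int
    block: Optional[int] = None


@dataclass
class StimulusSet:
    items: list[StimulusItem]
    design: DesignSpec

    def __len__(self) -> int:
        return len(self.items)

    def spellings(self, cell: Optional[str] = None) -> list[str]:
        return [it.spelling for it in self.items if cell is None or it.cell == cell]

    def subset(self, cell: str) -> "StimulusSet":
        return StimulusSet(
            [it for it in self.items if it.cell == cell], self.design
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spelling": [it.spelling for it in self.items],
                "cell": [it.cell for it in self.items],
                "match_group": [it.match_group for it in self.items],
                "block": [it.block for it in self.items],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# matching transforms
# ---------------------------------------------------------------------------

def _unit_split(spelling: str, inv: LetterInventory) -> tuple[str, str, str]:
    """Split off the initial prefix/control unit; returns (unit, kind, rest)."""
    units = sorted(
        [(p, "prefix") for p in inv.prefixes]
        + [(c, "control") for c in inv.prefix_controls],
        key=lambda t: -len(t[0]),
    )
    for unit, kind in units:
        if spelling.startswith(unit) and vowel_groups(spelling[len(unit):]):
            return unit, kind, spelling[len(unit):]
    raise TransformNotApplicableError(
        f"{spelling!r} does not begin with a prefix or control unit"
    )


def apply_transform(
    spelling: str,
    transform: str,
    inv: LetterInventory | None = None,
    rng: Optional[np.random.Generator] = None,
    choice: Optional[str] = None,
) -> str:
    """Apply one matching transform; raises
    :class:`TransformNotApplicableError` when the spelling is incompatible.

    For ``vowel_lengthen`` with two orthographic alternatives (e→ea/ee,
    u→oo/ou) the variant is drawn from ``rng`` when given, taken from
    ``choice`` when supplied, and defaults to the first alternative.
    """
    inv = inv or LetterInventory()
    if transform == "prefix_swap":
        unit, kind, rest = _unit_split(spelling, inv)
        mapping = dict(inv.prefix_pairs) if kind == "prefix" else {
            c: p for p, c in inv.prefix_pairs
        }
        return mapping[unit] + rest

    s = syllabify(spelling, inv)
    if transform == "vowel_lengthen":
        v = s.vowel2
        if v not in LENGTHEN_MAP:
            raise TransformNotApplicableError(f"second vowel {v!r} is not lengthenable")
        options = LENGTHEN_MAP[v]
        if choice is not None:
            if choice not in options:
                raise TransformNotApplicableError(
                    f"{choice!r} is not a long form of {v!r}"
                )
            long_v = choice
        elif rng is not None:
            long_v = options[int(rng.integers(len(options)))]
        else:
            long_v = options[0]
        return _replace_second_vowel(spelling, v, long_v)
    if transform == "vowel_shorten":
        v = s.vowel2
        if v not in SHORTEN_MAP:
            raise TransformNotApplicableError(f"second vowel {v!r} is not shortenable")
        return _replace_second_vowel(spelling, v, SHORTEN_MAP[v])
    if transform == "add_weight":
        return _add_weight(spelling, s, rng)
    raise ValueError(f"unknown transform {transform!r}")


def _replace_second_vowel(spelling: str, old: str, new: str) -> str:
    groups = vowel_groups(spelling)
    start, end = groups[1]
    assert spelling[start:end] == old
    return spelling[:start] + new + spelling[end:]


_WEIGHT_DOUBLINGS = {"l": "l", "s": "s", "n": "g"}  # coda -> appended letter
_WEIGHT_ONSETS = ("p", "s", "t")  # onset consonant -> digraph with following h


def _add_weight(
    spelling: str, s, rng: Optional[np.random.Generator]
) -> str:
    """Add one consonant letter to the second syllable, forming a final
    doubling (ll, ss, ng) or an initial/final digraph (ph, sh, th)."""
    candidates: list[str] = []
    last = spelling[-1]
    if last in _WEIGHT_DOUBLINGS:
        candidates.append(spelling + _WEIGHT_DOUBLINGS[last])
    if last in ("p", "t"):
        candidates.append(spelling + "h")
    groups = vowel_groups(spelling)
    v2_start = groups[1][0]
    onset_start = len(s.syllable1)
    if v2_start - onset_start == 1 and spelling[onset_start] in _WEIGHT_ONSETS:
        candidates.append(
            spelling[: onset_start + 1] + "h" + spelling[onset_start + 1:]
        )
    if not candidates:
        raise TransformNotApplicableError(
            f"no digraph or doubling applies to {spelling!r}"
        )
    if rng is not None:
        return candidates[int(rng.integers(len(candidates)))]
    return candidates[0]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_item(
    spelling: str,
    lex: Lexicon,
    inv: LetterInventory | None = None,
    design_id: str = "exp1",
) -> tuple[bool, list[str]]:
    """Check a candidate nonword against the construction constraints.

    Returns ``(valid, reasons)``; reasons name each failed check.
    """
    inv = inv or LetterInventory()
    reasons: list[str] = []
    lo, hi = LENGTH_RANGE[design_id]
    if not (lo <= len(spelling) <= hi):
        reasons.append(f"length {len(spelling)} outside {lo}-{hi}")
    try:
        s = syllabify(spelling, inv)
    except Exception as exc:
        reasons.append(f"not disyllabic: {exc}")
        return False, reasons
    if s.syllable1 in lex.monosyllable_set:
        reasons.append(f"first syllable {s.syllable1!r} is a monosyllabic word")
    if s.syllable2 in lex.monosyllable_set:
        reasons.append(f"second syllable {s.syllable2!r} is a monosyllabic word")
    if spelling in lex.spelling_set:
        reasons.append("spelling is a real word")
    return (not reasons), reasons


def _boundary_aligned(spelling: str, unit: str, inv: LetterInventory) -> bool:
    """The maximal-onset split must place the prefix/control unit exactly in
    the first syllable, as in mis.dut / mes.dut."""
    try:
        s = syllabify(spelling, inv)
    except Exception:
        return False
    return s.syllable1 == unit


# ---------------------------------------------------------------------------
# factorial generation
# ---------------------------------------------------------------------------

def _derive_cells(
    base: str, design_id: str, inv: LetterInventory, rng: np.random.Generator
) -> dict[str, str]:
    """Derive all cells of one match-group from its non-prefixed short base."""
    swap = lambda w: apply_transform(w, "prefix_swap", inv)
    if design_id == "exp1":
        long_np = apply_transform(base, "vowel_lengthen", inv, rng=rng)
        return {
            "nonprefixed_short": base,
            "prefixed_short": swap(base),
            "nonprefixed_long": long_np,
            "prefixed_long": swap(long_np),
        }
    if design_id == "exp2":
        heavy = apply_transform(base, "add_weight", inv, rng=rng)
        return {
            "nonprefixed_light": base,
            "prefixed_light": swap(base),
            "nonprefixed_heavy": heavy,
            "prefixed_heavy": swap(heavy),
        }
    if design_id == "exp3":
        heavy = apply_transform(base, "add_weight", inv, rng=rng)
        long_np = apply_transform(base, "vowel_lengthen", inv, rng=rng)
        return {
            "nonprefixed_short": heavy,
            "prefixed_short": swap(heavy),
            "nonprefixed_long": long_np,
            "prefixed_long": swap(long_np),
        }
    if design_id == "exp4":
        cued = swap(apply_transform(base, "vowel_lengthen", inv, rng=rng))
        return {"noncued": base, "cued": cued}
    raise ValueError(design_id)


def generate_factorial_set(
    spec: DesignSpec,
    lex: Lexicon,
    inv: LetterInventory | None = None,
    max_tries: int = 20_000,
    match_neighborhood: Optional[int] = None,
) -> StimulusSet:
    """Generate ``n_per_cell`` complete match-groups for the given design.

    Base skeletons are control-unit + C V C second syllables sampled from the
    consonant pool and rejection-sampled through :func:`validate_item`; every
    derived cell member must also validate and keep its unit aligned with the
    syllable boundary.  With ``match_neighborhood`` set, a match-group is
    only accepted when its members' Coltheart's N values (against ``lex``)
    span at most that range, keeping the cells group-wise comparable on
    neighbourhood size.  Deterministic given ``spec.seed``.
    """
    inv = inv or LetterInventory()
    rng = np.random.default_rng(spec.seed)
    items: list[StimulusItem] = []
    used: set[str] = set()
    controls = inv.prefix_controls
    group = 0
    tries = 0
    while group < spec.n_per_cell:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not build {spec.n_per_cell} match-groups in "
                f"{max_tries} draws"
            )
        unit = controls[int(rng.integers(len(controls)))]
        onset = CONSONANT_POOL[int(rng.integers(len(CONSONANT_POOL)))]
        vowel = sorted(inv.short_vowels)[int(rng.integers(len(inv.short_vowels)))]
        coda = CONSONANT_POOL[int(rng.integers(len(CONSONANT_POOL)))]
        base = unit + onset + vowel + coda
        try:
            cells = _derive_cells(base, spec.design_id, inv, rng)
        except TransformNotApplicableError:
            continue
        ok = True
        for spelling in cells.values():
            valid, _ = validate_item(spelling, lex, inv, spec.design_id)
            this_unit, _, _ = _unit_split(spelling, inv)
            if (not valid) or spelling in used or not _boundary_aligned(
                spelling, this_unit, inv
            ):
                ok = False
                break
        if not ok or len(set(cells.values())) != len(cells):
            continue
        if match_neighborhood is not None:
            from .lexicon import coltheart_n

            ns = [coltheart_n(w, lex) for w in cells.values()]
            if max(ns) - min(ns) > match_neighborhood:
                continue
        for cell, spelling in cells.items():
            items.append(StimulusItem(spelling, cell, group))
            used.add(spelling)
        group += 1
    return StimulusSet(items, spec)


# ---------------------------------------------------------------------------
# blocking
# ---------------------------------------------------------------------------

def assign_blocks(sset: StimulusSet, n_blocks: int, seed: int = 0) -> StimulusSet:
    """Divide a stimulus set into blocks so that every condition is equally
    represented within each block and no two members of a match-group share a
    block; within-block order is randomised by ``seed``.
    """
    cells = sset.design.cells
    n_groups = len(sset) // len(cells)
    if n_blocks < len(cells):
        raise GenerationError(
            f"{n_blocks} blocks cannot separate {len(cells)}-cell match-groups"
        )
    if len(sset) % n_blocks or n_groups % n_blocks:
        raise GenerationError(
            f"{len(sset)} items / {n_groups} groups not divisible by "
            f"{n_blocks} blocks"
        )
    cell_index = {c: i for i, c in enumerate(cells)}
    rng = np.random.default_rng(seed)
    blocks: dict[int, list[StimulusItem]] = {b: [] for b in range(n_blocks)}
    for it in sset.items:
        b = (it.match_group + cell_index[it.cell]) % n_blocks
        blocks[b].append(StimulusItem(it.spelling, it.cell, it.match_group, b))
    ordered: list[StimulusItem] = []
    for b in range(n_blocks):
        idx = rng.permutation(len(blocks[b]))
        ordered.extend(blocks[b][i] for i in idx)
    return StimulusSet(ordered, sset.design)


# ---------------------------------------------------------------------------
# sentence-experiment lists
# ---------------------------------------------------------------------------

COMBOS: tuple[tuple[str, str], ...] = (
    ("noun", "trochaic"), ("noun", "iambic"),
    ("verb", "trochaic"), ("verb", "iambic"),
)

#: minimum serial distance between members of a matched pair
MIN_PAIR_DISTANCE = 20
#: longest allowed run of a shared syntactic or rhythmic context
MAX_CONTEXT_RUN = 3


@dataclass
class ContextAssignment:
    """One pseudorandomised list for the sentence experiment."""

    list_id: int
    trials: list[dict]  # trial_index, spelling, cue_status, syntactic, rhythmic

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trials)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _context_runs_ok(labels: Sequence[tuple[str, str]]) -> bool:
    for axis in (0, 1):
        run = 1
        for prev, cur in zip(labels, labels[1:]):
            run = run + 1 if cur[axis] == prev[axis] else 1
            if run > MAX_CONTEXT_RUN:
                return False
    return True


def _build_template(
    n_pairs: int, rng: np.random.Generator, max_tries: int
) -> list[tuple[str, int]]:
    """Fixed condition-by-serial-position template shared by all four lists.

    Quarters 0/1 hold combos {0, 3} and quarters 2/3 hold combos {1, 2}
    (each with both cue statuses), which guarantees that the j-th slot of any
    condition and the j-th slot of its partner condition (the one holding the
    matched item) sit in opposite halves at least a quarter-length apart.
    """
    per_quarter = n_pairs // 8
    quarter_pools = {
        0: [("cued", 0), ("cued", 3), ("noncued", 0), ("noncued", 3)],
        2: [("cued", 1), ("cued", 2), ("noncued", 1), ("noncued", 2)],
    }
    for _ in range(max_tries):
        template: list[tuple[str, int]] = []
        ok = True
        for q in range(4):
            pool = quarter_pools[0 if q < 2 else 2]
            labels = [cond for cond in pool for _ in range(per_quarter)]
            for _ in range(200):
                idx = rng.permutation(len(labels))
                quarter = [labels[i] for i in idx]
                joined = template + quarter
                contexts = [COMBOS[c] for _, c in joined]
                if _context_runs_ok(contexts):
                    template = joined
                    break
            else:
                ok = False
                break
        if ok:
            return template
    raise GenerationError("could not build a context template within the retry budget")


def generate_exp4_lists(
    cued: StimulusSet,
    noncued: StimulusSet,
    seed: int = 0,
    max_tries: int = 200,
) -> list[ContextAssignment]:
    """Build the four pseudorandomised sentence-experiment lists.

    Items are matched by match-group across the cued and non-cued sets.  A
    Latin-square rotation puts every item into all four syntactic × rhythmic
    combinations across the lists, condition serial positions are identical
    in every list, matched pair members are at least ``MIN_PAIR_DISTANCE``
    trials apart, and no more than ``MAX_CONTEXT_RUN`` consecutive sentences
    share a syntactic or rhythmic context.
    """
    cued_by_group = {it.match_group: it.spelling for it in cued.items}
    nonc_by_group = {it.match_group: it.spelling for it in noncued.items}
    if set(cued_by_group) != set(nonc_by_group):
        raise GenerationError("cued and non-cued sets are not pairwise matched")
    pairs = sorted(cued_by_group)
    if len(pairs) % 8:
        raise GenerationError("number of matched pairs must be a multiple of 8")
    rng = np.random.default_rng(seed)
    template = _build_template(len(pairs), rng, max_tries)
    slots: dict[tuple[str, int], list[int]] = {}
    for pos, cond in enumerate(template):
        slots.setdefault(cond, []).append(pos)

    base_combo = {k: i % 4 for i, k in enumerate(pairs)}
    lists: list[ContextAssignment] = []
    for l in range(4):
        trials: list[Optional[dict]] = [None] * len(template)
        # pairs whose cued member lands in combo c this list, in stable order
        for c in range(4):
            members = [k for k in pairs if (base_combo[k] + l) % 4 == c]
            for j, k in enumerate(members):
                cpos = slots[("cued", c)][j]
                npos = slots[("noncued", (c + 2) % 4)][j]
                syn_c, rhy_c = COMBOS[c]
                syn_n, rhy_n = COMBOS[(c + 2) % 4]
                trials[cpos] = {
                    "list": l + 1, "trial_index": cpos,
                    "spelling": cued_by_group[k], "cue_status": "cued",
                    "match_group": k, "syntactic": syn_c, "rhythmic": rhy_c,
                }
                trials[npos] = {
                    "list": l + 1, "trial_index": npos,
                    "spelling": nonc_by_group[k], "cue_status": "noncued",
                    "match_group": k, "syntactic": syn_n, "rhythmic": rhy_n,
                }
        assert all(t is not None for t in trials)
        lists.append(ContextAssignment(l + 1, trials))
    return lists
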