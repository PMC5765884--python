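"""Slot-coded feed-forward print-to-stress network.

Orthographic input is represented by one-hot letter activations over a fixed
slot template and mapped through a layer of logistic hidden units onto two
stress output units normalised to sum to one.  Two input coding schemes are
available:

* ``left_aligned`` — letter *i* of the string occupies slot *i*, all strings
  aligned on their first letter;
* ``onset_rime`` — each syllable is segmented into onset (initial consonant
  graphemes) and rime (vowel plus following consonants), and the four
  constituents are routed to dedicated slot banks.

The coding scheme shapes what the network can learn: with onset/rime banks
the second vowel always lands in the same slots, so vowel-length regularities
are easy to pick up, whereas left alignment only partially aligns the second
syllable across words.  Training is plain online stochastic gradient descent
on cross-entropy, in a seeded shuffled order, so runs are exactly
reproducible.  The training regime (disyllables only vs. monosyllables mixed
in) is recorded on the trained network because it changes what prefix-like
onsets predict: many monosyllables begin with prefix-spelling sequences yet
carry trivial first-syllable stress, diluting the prefix-to-final-stress
association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ..errors import EncodingError, StressCueError
from ..orthography import LetterInventory, syllabify, vowel_groups

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"
_LETTER_INDEX = {ch: i for i, ch in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class SlotCode:
    """One-hot letter activations over a fixed slot template."""

    scheme: str
    vector: np.ndarray
    n_slots: int

    def __post_init__(self) -> None:
        per_slot = self.vector.reshape(self.n_slots, len(_ALPHABET))
        if (per_slot.sum(axis=1) > 1).any():
            raise EncodingError("more than one active letter in a slot")


def _one_hot(letters: str, n_slots: int, label: str) -> np.ndarray:
    if len(letters) > n_slots:
        raise EncodingError(
            f"{label} {letters!r} exceeds its {n_slots}-slot bank"
        )
    out = np.zeros((n_slots, len(_ALPHABET)))
    for i, ch in enumerate(letters):
        out[i, _LETTER_INDEX[ch]] = 1.0
    return out.ravel()


def _split_onset_rime(syllable: str) -> tuple[str, str]:
    groups = vowel_groups(syllable)
    if not groups:
        return syllable, ""
    start = groups[0][0]
    return syllable[:start], syllable[start:]


#: slot counts per bank for the onset/rime template
ONSET_SLOTS = 3
RIME_SLOTS = 5


def slot_encode(
    spelling: str,
    scheme: str = "left_aligned",
    inv: LetterInventory | None = None,
    max_letters: int = 8,
) -> SlotCode:
    """Encode a letter string under the requested slot scheme.

    ``left_aligned`` uses ``max_letters`` ordinary letter slots.
    ``onset_rime`` syllabifies the string and fills four banks
    (onset1, rime1, onset2, rime2); a monosyllabic string fills the first
    two banks and leaves the second-syllable banks vacant.
    """
    inv = inv or LetterInventory()
    if scheme == "left_aligned":
        if len(spelling) > max_letters:
            raise EncodingError(f"{spelling!r} longer than {max_letters} slots")
        return SlotCode("left_aligned", _one_hot(spelling, max_letters, "string"),
                        max_letters)
    if scheme == "onset_rime":
        n_groups = len(vowel_groups(spelling))
        if n_groups == 2:
            s = syllabify(spelling, inv)
            o1, r1 = _split_onset_rime(s.syllable1)
            o2, r2 = _split_onset_rime(s.syllable2)
        elif n_groups == 1:
            o1, r1 = _split_onset_rime(spelling)
            o2, r2 = "", ""
        else:
            raise EncodingError(f"{spelling!r} has {n_groups} vowel groups")
        vec = np.concatenate([
            _one_hot(o1, ONSET_SLOTS, "onset1"),
            _one_hot(r1, RIME_SLOTS, "rime1"),
            _one_hot(o2, ONSET_SLOTS, "onset2"),
            _one_hot(r2, RIME_SLOTS, "rime2"),
        ])
        return SlotCode("onset_rime", vec, 2 * (ONSET_SLOTS + RIME_SLOTS))
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class StressNetwork:
    """A trained input → hidden → 2-output stress network."""

    scheme: str
    max_letters: int
    hidden: int
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    seed: int
    regime: str  # "disyllables_only" | "mono_plus_di"
    inv: LetterInventory = field(default_factory=LetterInventory)
    training_curve: list[float] = field(default_factory=list)

    def encode(self, spelling: str) -> np.ndarray:
        return slot_encode(spelling, self.scheme, self.inv, self.max_letters).vector

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = 1.0 / (1.0 + np.exp(-(self.W1 @ x + self.b1)))
        z = self.W2 @ h + self.b2
        z = z - z.max()
        e = np.exp(z)
        return h, e / e.sum()

    def save(self, path) -> None:
        np.savez(
            path,
            W1=self.W1, b1=self.b1, W2=self.W2, b2=self.b2,
            meta=np.array([self.scheme, self.regime, str(self.seed),
                           str(self.max_letters)], dtype=object),
        )


def train_network(
    lex,
    scheme: str = "left_aligned",
    hidden: int = 100,
    learning_rate: float = 0.1,
    epochs: int = 200,
    seed: int = 0,
    regime: str = "disyllables_only",
    max_letters: int = 8,
    inv: LetterInventory | None = None,
) -> StressNetwork:
    """Train the print-to-stress network on a lexicon.

    ``regime="mono_plus_di"`` appends the lexicon's monosyllables to the
    training set with first-syllable (trivial) stress targets.  Entries that
    do not fit the slot template are skipped with a warning.  Identical seed,
    data and hyperparameters give bit-identical weights.
    """
    inv = inv or LetterInventory()
    items: list[tuple[str, int]] = [(e.spelling, e.stress) for e in lex.entries]
    if regime == "mono_plus_di":
        items += [(w, 1) for w in lex.monosyllables]
    elif regime != "disyllables_only":
        raise ValueError(f"unknown training regime {regime!r}")

    encoded: list[tuple[np.ndarray, int]] = []
    skipped: list[str] = []
    for spelling, stress in items:
        try:
            encoded.append(
                (slot_encode(spelling, scheme, inv, max_letters).vector, stress - 1)
            )
        except (EncodingError, StressCueError):
            skipped.append(spelling)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} non-encodable training items "
            f"(e.g. {skipped[:3]})",
            stacklevel=2,
        )
    if not encoded:
        raise StressCueError("no encodable training items")

    dim = encoded[0][0].size
    rng = np.random.default_rng(seed)
    net = StressNetwork(
        scheme=scheme,
        max_letters=max_letters,
        hidden=hidden,
        W1=rng.normal(0.0, 0.1, size=(hidden, dim)),
        b1=np.zeros(hidden),
        W2=rng.normal(0.0, 0.1, size=(2, hidden)),
        b2=np.zeros(2),
        seed=seed,
        regime=regime,
        inv=inv,
    )
    X = np.stack([x for x, _ in encoded])
    y = np.array([t for _, t in encoded])
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        loss = 0.0
        for i in order:
            x = X[i]
            h, p = net.forward(x)
            target = np.array([1.0 - y[i], float(y[i])])
            loss -= float(np.log(p[y[i]] + 1e-12))
            delta_out = p - target
            delta_h = (net.W2.T @ delta_out) * h * (1.0 - h)
            net.W2 -= learning_rate * np.outer(delta_out, h)
            net.b2 -= learning_rate * delta_out
            net.W1 -= learning_rate * np.outer(delta_h, x)
            net.b1 -= learning_rate * delta_h
        net.training_curve.append(loss / n)
    return net


def network_stress(net: StressNetwork, spelling: str) -> tuple[float, int]:
    """Normalised second-syllable-stress activation and the binary decision
    (larger activation wins; an exact tie goes to first-syllable stress)."""
    _, p = net.forward(net.encode(spelling))
    p_s2 = float(p[1])
    return p_s2, (2 if p_s2 > 0.5 else 1)
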