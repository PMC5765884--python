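"""Sequential Bayesian combination of sublexical cues for stress assignment.

The reader is modelled as starting from a prior belief that a disyllable
takes second-syllable stress — the base rate in the corpus (about .27 for
English disyllables) — and revising that belief cue by cue.  Each sublexical
cue (a prefix, a long second vowel, a heavier second syllable) updates the
running posterior through Bayes' rule

    P(s2 | cue) = P(s2) * P(cue | s2) / (P(s2) P(cue|s2) + P(s1) P(cue|s1)),

with the posterior after one cue serving as the prior for the next.  A
nonword carrying none of the cues keeps the corpus prior unchanged: in the
default configuration only *present* cues carry evidence, so the posterior
of a cue-less item (e.g. *mesdut*) equals the prior exactly.  Because the
update multiplies likelihood ratios on the odds scale, the result does not
depend on the order in which the cues are considered.

The cue conditionals assume conditional independence of the three cues given
the stress class (naive sequential Bayes); this is an assumption of the
implementation, documented rather than derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from ..errors import DegenerateProbabilityError, ParameterError
from ..orthography import CueProfile, LetterInventory

#: default staging of the cues
DEFAULT_CUE_ORDER = ("prefix", "vowel_length", "weight")


@dataclass(frozen=True)
class BayesParams:
    """Prior and per-cue conditional likelihood tables.

    ``tables[cue][state] = (P(state | stress=2), P(state | stress=1))``.
    ``update_on_absent`` switches between evidence from present cues only
    (the default, which leaves cue-less items at the prior) and full
    naive-Bayes updating on every cue state.
    """

    prior_s2: float
    tables: dict[str, dict[str, tuple[float, float]]]
    cue_order: tuple[str, ...] = DEFAULT_CUE_ORDER
    present_states: dict[str, str] = field(
        default_factory=lambda: {
            "prefix": "present",
            "vowel_length": "long",
            "weight": "pos",
        }
    )
    update_on_absent: bool = False

    def to_json(self, path) -> None:
        payload = {
            "prior_s2": self.prior_s2,
            "tables": {
                cue: {state: list(ps) for state, ps in table.items()}
                for cue, table in self.tables.items()
            },
            "cue_order": list(self.cue_order),
            "present_states": self.present_states,
            "update_on_absent": self.update_on_absent,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BayesParams":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            prior_s2=raw["prior_s2"],
            tables={
                cue: {state: tuple(ps) for state, ps in table.items()}
                for cue, table in raw["tables"].items()
            },
            cue_order=tuple(raw["cue_order"]),
            present_states=raw["present_states"],
            update_on_absent=raw["update_on_absent"],
        )


def bayes_update(prior: float, like_s2: float, like_s1: float) -> float:
    """One stage of the sequential update:
    ``prior·like_s2 / (prior·like_s2 + (1 − prior)·like_s1)``."""
    for name, p in (("prior", prior), ("like_s2", like_s2), ("like_s1", like_s1)):
        if not 0.0 < p < 1.0:
            raise DegenerateProbabilityError(f"{name}={p} must lie strictly in (0, 1)")
    num = prior * like_s2
    return num / (num + (1.0 - prior) * like_s1)


def bayes_posterior(profile: CueProfile, params: BayesParams) -> float:
    """Posterior probability of second-syllable stress for one cue profile.

    Cues are applied in ``params.cue_order``, each stage's posterior becoming
    the next stage's prior.  With ``update_on_absent=False`` a cue in its
    absent/neutral state contributes no evidence.
    """
    from ..lexicon import cue_states  # local import avoids a module cycle

    states = cue_states(profile)
    posterior = params.prior_s2
    for cue in params.cue_order:
        if cue not in params.tables:
            raise ParameterError(f"no conditional table for cue {cue!r}")
        state = states[cue]
        if state not in params.tables[cue]:
            raise ParameterError(f"no conditional for state {state!r} of cue {cue!r}")
        if not params.update_on_absent and state != params.present_states.get(cue):
            continue
        like_s2, like_s1 = params.tables[cue][state]
        posterior = bayes_update(posterior, like_s2, like_s1)
    return posterior


def bayes_classify(posterior: float, threshold: float = 0.5) -> int:
    """Binary stress decision: 2 iff the posterior exceeds the threshold;
    ties go to first-syllable stress (the majority pattern)."""
    return 2 if posterior > threshold else 1


def estimate_bayes_params(
    lex, inv: Optional[LetterInventory] = None, **kwargs
) -> BayesParams:
    """Estimate :class:`BayesParams` from a corpus (prior plus smoothed
    conditional tables); extra keyword arguments override fields such as
    ``update_on_absent`` or ``cue_order``."""
    from ..lexicon import cue_likelihoods

    params = cue_likelihoods(lex, inv or LetterInventory())
    if kwargs:
        from dataclasses import replace

        params = replace(params, **kwargs)
    return params
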