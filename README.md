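# stresscue

Modeling how readers place **lexical stress** on unfamiliar English
disyllables from the letter string alone.

When an English reader meets a nonword like *preleal* or *pralel*, they must
decide whether to stress the first or the second syllable (*CA-mel* vs.
*ca-NAL*) with no lexical entry to consult.  Behavioural work shows that
three sublexical cues drive this decision:

* **prefixation** — an initial unit spelled like a prefix (*de-*, *mis-*,
  *pre-*, *re-*) attracts second-syllable stress;
* **vowel length** — a long second vowel (digraphs *ai, ea, ee, oa, oo, ou*)
  attracts stress;
* **orthographic weight** — a second syllable with more letters attracts
  stress.

`stresscue` implements, as one tested pipeline, everything needed to study
these cues computationally: factorial nonword construction with pairwise
matching, corpus covariates, three competing stress models, and the
model-vs-reader evaluation machinery.  A synthetic-lexicon generator and a
simulated reading-aloud cohort stand in for proprietary corpora (CELEX) and
human data, so every stage is runnable and testable end to end.

## The models

**Affix rule cascade** (`rc00_stress`): prefix found → stress 2; else a
stress-taking suffix (*-een, -ique, -oo*) → stress 2; else any other suffix →
stress 1; else the English default, stress 1.  Deterministic and all-or-none.

**Sequential Bayesian cue combination** (`bayes_posterior`): start from the
corpus prior P(stress₂) ≈ .27 and update it cue by cue,

    P(s₂ | cue) = P(s₂) P(cue | s₂) / [ P(s₂) P(cue | s₂) + P(s₁) P(cue | s₁) ],

each stage's posterior feeding the next stage as its prior.  A nonword
carrying none of the cues keeps the prior exactly.  Because each stage
multiplies the odds by a likelihood ratio, the result is invariant to cue
order.

**Slot-coded print-to-stress network** (`train_network`): one-hot letters in
a fixed slot template (left-aligned, or onset/rime banks per syllable) feed
a logistic hidden layer and two normalised stress outputs, trained by online
SGD on cross-entropy.  The training regime (disyllables only vs.
monosyllables mixed in) is a first-class experimental variable.

Model predictions are compared with (simulated) readers' **modal stress**
per item via 2×2 contingency tables, signal-detection sensitivity
d′ = z(H) − z(F) and bias c = −(z(H) + z(F))/2 (first-syllable stress as
the signal class; negative c = bias toward first-syllable stress),
agreement percentages, and logistic regressions on cue indicators with
explicit complete-separation detection.

## Worked example

```python
from dataclasses import replace
import stresscue as sc

lex = sc.generate_lexicon(sc.LexiconConfig(n_disyllables=3000, seed=1))
params = replace(sc.estimate_bayes_params(lex), prior_s2=0.27)
for w in ("mesdut", "misdut", "misdoot"):
    p = sc.cue_profile(w)
    print(w, p.has_prefix, p.second_vowel_length, p.weight_diff,
          round(sc.bayes_posterior(p, params), 3))
```

prints

```
mesdut  False short 0  0.27
misdut  True  short 0  0.397
misdoot True  long  1  0.477
```

*mesdut* carries no cue, so its posterior is exactly the prior (.27).
*misdut* adds the prefix *mis-*, raising the posterior; *misdoot* adds a
long vowel and a heavier second syllable on top.  The absolute values for
cued items depend on the corpus the conditionals are estimated from — here
a synthetic lexicon; a corpus with a stronger prefix–stress association
pushes *misdut* correspondingly higher.

The rule model, in contrast, is all-or-none:

```python
sc.rc00_stress("preleal")  # 2  (prefix found)
sc.rc00_stress("pralel")   # 1  (no affix: English default)
```

A full experiment — stimulus generation, simulated cohort, all three
models, proportion tables, regressions, and d′/c — is one call
(`sc.run_experiment("exp1", lex, seed=7)`) or one shell command
(`stresscue run-experiment --design exp1 --lexicon lex.csv --seed 7
--out results/`).

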