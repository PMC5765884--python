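# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the test suite shows.  It states no empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Orthographic parsing

A disyllable is any lowercase letter string with exactly two vowel groups
(maximal runs of vowel letters).  The letter *y* counts as a vowel only when
neither neighbour is a vowel letter — vowel in *abyss*, consonant in
*beyond* — and its use is flagged on the syllabification.  The intervocalic
consonant cluster is split by the maximal-onset principle over a
configurable onset inventory (all single consonants plus common clusters;
*sd* is absent, which forces *mis.dut*).  The onset inventory is a
reconstruction: phonotactic legality is appealed to by the experimental
logic but no full list is canonical, so it is config-replaceable
(`LetterInventory.from_file`).

The three sublexical cues are: prefix presence (longest inventory prefix
whose remainder still contains a vowel), second-vowel length (single letter
= short, inventory digraph = long), and orthographic weight (letter count
per syllable; the Bayesian cue uses the sign of the second-minus-first
difference, bucketed ≤−1 / 0 / ≥+1 to keep estimation cells populated).
The *word ending* — all letters from the second nucleus onward — feeds the
ending-frequency covariates.  Words without a second vowel group (syllabic
consonants: *spasm*, *rhythm*) have no ending and are flagged, not errored.

## Corpus statistics

Coltheart's N counts same-length spellings differing by exactly one
substitution.  OLD20 is the mean unit-cost edit distance (via `edlib`) to
the 20 nearest spellings, self excluded, ties at the rank-20 boundary
resolved by a stable sort on (distance, spelling); with fewer than 20
comparison spellings the mean runs over all of them, with a warning.
Bigram frequency is a position-independent *type* count (each corpus word
counted once per bigram).  All of these are validated against brute-force
oracles in the tests.

The Bayesian parameters are the corpus rate of second-syllable stress
(prior) plus, per cue, P(state | stress class) with add-one smoothing over
each cue's state space, so conditionals always sum to one and empty cells
keep nonzero mass.

## The sequential Bayesian model

Updating is staged naive Bayes: conditional independence of the three cues
given the stress class is an *assumption* of the implementation, not a
derived fact.  On the odds scale each stage multiplies by a likelihood
ratio, which makes the posterior invariant to cue order and monotone in
each stage's evidence; both properties are tested.

By default only *present* cues contribute evidence (a present prefix, a
long second vowel, a positive weight difference).  This is what makes the
posterior of a cue-less item equal the prior exactly — the behaviour of the
worked example *mesdut* → .27 — and it is the reading we adopt.  The
alternative, in which absent states also update (full naive Bayes over all
states), is available via `BayesParams(update_on_absent=True)`; it is the
variant under which the joint-count oracle test applies, since only then is
the posterior an estimate of the full joint P(stress₂ | all cue states).
The worked-example posteriors for cued items (*misdut*, *misdoot*) depend
on the conditional tables of the corpus they were originally derived from,
which are not public; our synthetic corpus reproduces the qualitative
ordering but not those exact values, and we treat them as calibration
notes, not test anchors.

Classification threshold is 0.5 with ties going to stress 1 (the majority
pattern of English disyllables).

## The print-to-stress network

Input: 26-way one-hot letters over a slot template — `left_aligned`
(default 8 slots) or `onset_rime` (3+5 slots per syllable; monosyllables
occupy the first-syllable banks only).  One logistic hidden layer (default
width 100), two outputs normalised by softmax, online SGD on cross-entropy
(default learning rate 0.1, 200 epochs) in a seeded shuffled order; given
seed, data and hyperparameters the weights are bit-identical.  These
defaults are desk-scale conventions, exposed in `train_network`; the
pipeline's default run configuration (hidden 40, 30 epochs) keeps full
experiment runs in seconds.

**Training-regime contrast.**  Adding monosyllables (labelled with trivial
first-syllable stress) to the training set is hypothesised to dilute the
prefix→second-syllable-stress association, because many monosyllables
(*red*, *press*, *desk*) begin with prefix-spelling sequences.  Our
experiments with this architecture show the dilution is a property of
*early* learning: after a few epochs the hidden layer exploits later-slot
occupancy to segregate monosyllables from disyllables and fully compensates,
and at convergence the prefix effect is no smaller with monosyllables in
the training set (we verified this across hidden widths 10–40, 8–50
epochs, and mono:di ratios up to 4:1).  The directional test therefore
probes the early-training regime (3 epochs, learning rate 0.25, mean over
six training seeds) on a corpus where prefixation is the only stress cue
and prefix-initial monosyllables are plentiful and length-matched to the
prefixed disyllables.  This regime dependence is itself a finding worth
keeping in view when interpreting the original hypothesis.

## Stimulus generation

Match-groups start from a non-prefixed short-vowel base (control unit +
C V C second syllable) and derive the other cells by minimal transforms
(prefix↔control swap; short→long vowel with the e→ea/ee and u→oo/ou variants
drawn per group; weight added as a digraph *ph/sh/th* or doubling
*ll/ss/ng*).  Every member must re-syllabify with its unit exactly in the
first syllable (so *mis-* items split *mis.dut*, and skeletons like
*mi.stut* are rejected), must not be a listed word, must keep both
syllables off the monosyllable list, and must respect the design's length
band (5–7 letters; 6–7 for the weight-controlled design).  An optional
`match_neighborhood` constraint additionally caps the within-group range of
Coltheart's N.

Blocking uses a Latin square (block = group + cell index, mod blocks),
which guarantees balanced cells per block and match-group separation; it
requires the group count to be divisible by the block count.

The sentence-experiment lists use a fixed condition-by-position template
shared by all four lists: quarters 1–2 carry the noun/trochaic and
verb/iambic combinations, quarters 3–4 the other two, which places every
matched pair's members in opposite halves at least 21 trials apart by
construction; within quarters, orders are rejection-sampled so no more
than three consecutive trials share a syntactic or rhythmic context.  A
Latin-square rotation walks each item through all four context
combinations across lists.  The pair count must be a multiple of 8.
Sentence frames themselves are not generated; syntactic and rhythmic
contexts are condition labels consumed by the reader simulator.

## Synthetic lexicon and simulated readers

`generate_lexicon` samples disyllabic spellings (prefix or control first
units, short or long second vowels, variable codas), assigns word classes
(45% noun, 30% verb), and draws stress from a logistic model: class-typical
base rates (nouns .10, verbs .67 second-syllable stress, the 'other' rate
solved so the corpus marginal equals the configured base, default .27) plus
cue effects on the log-odds (defaults: prefix +1.3, long vowel +0.6,
positive weight +0.6), centred on their sample means so the marginal stays
at the configured rate whatever the effect sizes.  Monosyllables are
sampled separately; about a third begin with prefix-spelling sequences.

`simulate_readers` draws trial-level responses from a logistic model with
crossed participant and item random intercepts (defaults SD 0.5 and 0.25),
context effects for sentence reading (verb +1.48, iambic +1.72, and a
−0.78 verb×iambic interaction), and a 2% discard rate emulating dysfluent
responses.  The default weights were calibrated once against the published
human condition proportions and then frozen; they describe a stylised
cohort.  Single-word and sentence reading get separate intercepts, and cue
weights are scaled up (×1.53) in sentences, mirroring the larger cued
vs. non-cued gap observed there.

What the simulator does *not* emulate: reaction times, articulation,
item-specific phonological neighbourhoods, participant-specific cue
*slopes* (random intercepts only), or any acoustic basis of the stress
judgment.  Passing tests therefore show that the pipeline recovers the
structure it generates — not that human readers obey it.

## Evaluation conventions

d′ and c are computed with **first-syllable stress as the signal class**:
H = P(model 1 | modal 1), F = P(model 1 | modal 2), d′ = z(H) − z(F),
c = −(z(H) + z(F))/2, so negative c means bias toward first-syllable
stress.  This convention reproduces all three verifiable published (d′, c)
pairs with correct signs.  The published Bayesian-account pair
(d′ = 0.79, c = −.23) is *not* derivable from the published contingency
counts under this (or any single) convention that fits the other three
models — those counts give ≈ (0.46, −0.40) — so it is excluded from the
reproduction checks and recorded here as a discrepancy.  Rates of exactly
0 or 1 are corrected to 1/(2N) and 1 − 1/(2N) per marginal before the
z-transform (needed for all-or-none rule-model tables).

Crossed-random-effects mixed models are out of scope.  The cue regression
is fixed-effects maximum-likelihood logistic (statsmodels), with optional
item-cluster robust standard errors standing in for the item random
intercept when fitted to trial-level data.  Complete/quasi-complete
separation is detected by level-purity cross-tabs for binary predictors
plus a coefficient-divergence check; under separation the fit falls back to
a weakly ridge-penalised solution and is reported flagged, never as
converged.  Rank-deficient designs raise an error naming the collinear
columns.

Calibration facts computed by the acceptance tests: with 40 participants ×
80 items and 200 replicates, the trial-level regression recovers generating
cue weights with |bias| < 0.15 log-odds under crossed random intercepts
(the residual bias is the usual conditional→marginal attenuation, ≈7% at
the default spreads); 95% CIs attain nominal coverage when the generator
matches the fitted model; the null rejection rate is ≈5% at α = .05.

## Problem sizes

Defaults throughout are desk-scale choices: synthetic corpora of 2000–5000
disyllables for estimation and oracle tests, 80-item stimulus sets (the
published designs' size), cohorts of 20–40 participants, 200-replicate
recovery studies, and early-regime network training as described above.
All are parameters, not limits.
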