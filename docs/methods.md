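# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `careinsight`, in the spirit of a model-description
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A corpus is a set of documents with seven ordinal labels each: an overall
care-need level 0–5 and six module levels 0–4 (mobility, cognitive and
communication skills, behavioral problems, self-sufficiency, self-therapy,
everyday life). The coarse view maps every label with 0→0; 1,2→1; 3,4,5→2;
all explanation experiments run on the coarse 3-class setting, where
classifiers are stronger and class-wise attribution is tractable.

Splitting is deterministic: ids are shuffled by seed, validation and test
receive `floor(N·fraction)` ids, and train absorbs the remainder. The
fractions 0.70/0.10/0.20 reproduce 50,876/7,268/14,536 on 72,680 ids
exactly. Word tokenization lowercases, splits on whitespace and strips
punctuation, keeping intra-word hyphens (German compounds).

## Synthetic corpus generator

The generator is the package's stand-in for private assessment corpora: every
downstream claim is tested against its planted ground truth.

* **Documents** are filler words drawn i.i.d. from a Zipf distribution over a
  pseudo-word vocabulary (default 2,000 types, exponent 1.1), with ~25%
  German stop words mixed in so stop-word handling is exercised. Default
  corpus: 3,000 documents of mean length 200 words (SD 50).
* **Signal phrases.** Each module owns 18 exclusive 1–3-word phrases with
  target frequencies tiered from 10% of the corpus down to one singleton —
  mirroring how a real instrument scores many distinct criteria per module,
  some ubiquitous and some rare. Two shared phrases are planted across all
  six modules; their importance spreads over all tasks, giving them maximal
  entropy, which is exactly the structure homogeneity weighting must
  down-rank. Planted signal words are corrupted to edit-distance-1 typo
  variants with probability 0.02.
* **Severity latent.** Each document draws a global gamma severity and one
  per-module gamma severity (both mean 1); a module's planting probabilities
  scale with `0.5·global + 0.5·module`. The global component correlates
  impairment across areas of life — severe applicants score high in several
  modules, which is what makes high care-need levels reachable — while the
  module component keeps tasks statistically separable.
* **Labels.** Module level = `min(4, floor(α · weighted signal count))` with
  α = 1 by default, so the planted phrases are by construction the only
  cause of the labels. Care need is the module-weight aggregate (defaults
  0.10/0.075/0.075/0.40/0.20/0.15, echoing the instrument's weighting of
  self-sufficiency above the rest) rescaled to 0–5 and rounded. An optional
  label-flip rate exists for noise experiments and defaults to 0.
* **Registry.** Every planting event is recorded with document, position and
  realized (possibly typo-corrupted) words; recovery metrics count a ranked
  phrase as a hit when it contains at least one planted exclusive signal
  word of the task. The overall care-need task has no phrases of its own (its
  label is derived), so its hit set is the union of all module signal words.

What the generator does **not** model: grammar, discourse structure, semantic
similarity between phrase variants, section structure of real notes, or
assessor style. Passing tests therefore demonstrate that the pipeline
recovers planted lexical signal under realistic frequency and correlation
structure — not that it handles paraphrase or negation in real clinical text.

## Bag-of-words baseline

TF-IDF (smoothed logarithmic idf, L2 document normalization) over 1–3-grams
with min document frequency 2 and max document frequency 0.3·N, stop words
excluded; one-vs-rest ridge classifiers (α = 1.0) per task. Both
document-frequency bounds are counted on raw documents. Attribution is the
exact linear decomposition `coef[class] ⊙ tfidf(doc)`; the naive global
variant multiplies coefficients with the mean training input and equals the
mean of per-sample attributions by linearity — the test suite asserts both
identities. Global aggregation over a corpus is computed by sparse matrix
algebra (per task, documents grouped by predicted class) rather than by
materializing per-sample records, which is algebraically identical.

## Segment transformer

A small BERT-style encoder implemented in numpy on a reverse-mode autodiff
core (`nn.py`): token + position embeddings, post-layer-norm blocks with
multi-head softmax attention and GELU feed-forward, all float64. Long
documents are split into overlapping windows (default 512 subtokens, stride
window/2, so every position lies in at most two segments; desk-scale
experiments use window 64). Each segment is encoded independently; the
document representation is `layernorm(concat(mean, max))` over masked-mean
segment representations — concatenation rather than summation of the two
pools, flagged as a choice. One linear head per task.

Subtokens come from a byte-pair encoder trained on the training split
(greedy highest-count merges, deterministic lexicographic tie-break), which
reproduces the subtoken-merging problem phrase construction must solve.

Training minimizes the unweighted sum of per-task cross-entropies with Adam,
one document per step, model selection on validation care-need macro-F1.
Ten percent of training subtokens are replaced by the mask token each epoch.
This masking noise is what makes token-removal evaluation meaningful for a
from-scratch encoder: without it the mask token is out-of-distribution at
evaluation time and masking can move predictions arbitrarily — pretrained
models get the same property from their masked-language-model pretraining.
Training aborts with diagnostics when the loss becomes non-finite or
explodes past 1e8. A truncation variant encodes only the first window and is
used for the architecture ablation.

Desk-scale configuration used by the tests and the acceptance script:
500 documents of ~110 words, window 64, stride 32, model dim 32, 2 layers,
2 heads, feed-forward dim 64, 4 epochs — chosen as the smallest setting at
which the classifiers clearly beat majority baselines and the ablation
contrasts are stable.

## Attribution methods

All methods emit one score per document subtoken; overlapping segments are
stitched by averaging scores at shared positions.

* **Attention rollout** — per layer, heads are averaged, the identity is
  mixed in with residual weight 0.5, rows renormalized, and layers composed
  by matrix product; a position's score is the attention it receives from
  valid query positions. Task- and class-agnostic, non-negative.
* **Gradient × Activation** — embedding activations times the gradient of
  the explained class logit, summed (signed) over embedding dimensions. The
  signed sum, rather than an L2 norm, keeps the downstream "discard
  negatives" rule meaningful.
* **Integrated Gradients** — midpoint Riemann approximation of the path
  integral from a baseline (padding-token embeddings by default, zeros
  optional; 64 steps by default) times input-minus-baseline. Completeness —
  attributions summing to logit(input) − logit(baseline) — is asserted in
  the tests at 512 steps to below 1% of the logit range, and exactly (any
  step count) on a purely linear toy model.
* **LRP** — epsilon rule (ε = 1e-6) for all linear maps; residual sums split
  relevance proportionally to the two summands; attention weights act as
  constant mixing matrices (value path only; queries/keys receive nothing);
  layer norms pass relevance through unchanged. Conservation is exact up to
  epsilon slack and bias absorption; the conservation test uses a zero-bias
  fixture, where the measured error is far below the 5% tolerance. Stitching
  by averaging breaks exact conservation for multi-segment documents, so
  conservation is asserted on single-segment inputs.

Explanations default to the predicted class (the ground-truth class is a
caller choice), including in the risk-factor analysis of over-estimated
predictions.

## Phrase construction and aggregation

Subtoken scores are summed per word; every contiguous 1–3-gram passes unless
it consists solely of stop words (unigrams must not be stop words); the
phrase score is the arithmetic mean of its word scores, so a strong unigram
can outrank its own bigrams. Negative occurrence scores are dropped, and
positive occurrences of the same phrase within one document are summed into
a single record so the sample index of the aggregation formulas indexes
documents. Entropy uses the natural logarithm — only rankings matter after
min-max normalization. H_min/H_max are computed once over all phrases pooled
across tasks; if the range is degenerate the homogeneity weight is 1 for all
phrases (the formula's limit). Ranked tables break ties by support
(descending) then phrase (lexicographic); occurrence counts are document
frequencies in the corpus, and an optional minimum-occurrence cutoff is
exposed. Risk-factor tables filter to documents whose prediction exceeds the
ground truth for a task, group by the (true, predicted) pair, and aggregate
each group with homogeneity weighting.

## Faithfulness evaluation

"Removal" is replacement with the mask token, preserving positions and
avoiding position-shift confounds; for the bag-of-words model the feature is
zeroed. The local protocol masks each document's next-ranked subtokens in
steps of token *counts* (default 5 at a time up to 20, per-document capped),
following the one-by-one removal idea; a 100%-removal point is appended,
where every ranking must coincide because all inputs are identical. The
random baseline uses seeded per-document permutations and is averaged over
five seeds for curve comparisons; curves are computed on the full held-out
split, since macro-F1 over few documents is too volatile for per-step
comparisons. The global protocol (AOPC) expands a phrase ranking into its
constituent words, masks all their subtokens cumulatively, and averages the
ground-truth-class logit drop over evaluation documents (500 by default;
desk-scale runs use 40).

## Known limitations

* The encoder trains from scratch on synthetic text; no pretrained weights
  are involved (a checkpoint hook exists in the config). Absolute F1 values
  are therefore not comparable to pretrained-model results — only orderings
  and contrasts are meaningful.
* LRP conservation degrades gracefully (bias absorption, overlap averaging)
  on trained multi-segment models; the exact-property tests pin it on
  controlled fixtures.
* Phrase tables contain redundant variants of the same underlying phrase
  (sub-n-grams, typo variants); no semantic clustering is attempted.
* The local-removal dominance of attribution over random ranking is a
  statistical property: on weakly trained models individual steps can cross
  within noise, which is why curve comparisons average the random baseline
  over seeds and use the full evaluation split.
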