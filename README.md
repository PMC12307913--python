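# careinsight

Extracting dataset-level insight phrases from multi-task text classifiers via
feature-attribution aggregation.

## The problem

German long-term-care benefits are allocated after a standardized assessment:
a care professional scores six modules covering areas of daily life
(mobility, cognitive and communication skills, behavioral problems,
self-sufficiency, self-therapy, everyday life, each 0–4) whose weighted
aggregate determines the overall care-need level (0–5). Alongside the scores,
assessors write long free-text notes. Those notes encode which concrete
circumstances of a person's life drive the assessment — but reading tens of
thousands of them by hand is impossible.

`careinsight` implements a workflow for mining such corpora without any phrase
annotation: train per-task classifiers on the notes, attribute each
prediction back to its input tokens, merge token attributions into 1–3-word
phrases, and aggregate phrase attributions globally per task. The output is a
ranked table of phrases per module — e.g. which formulations assessors use
when mobility is impaired — plus a "risk factor" view of phrases that drive
over-estimated predictions.

Because real assessment data is private, the package ships a first-class
synthetic-corpus generator that emulates its structure (long documents,
seven correlated ordinal tasks, planted task-specific signal phrases of
known frequency, typo variants, filler text) and records all plantings in a
registry, so every downstream stage is testable against known ground truth.

## The method

Two model families are supported:

* **Bag-of-words baseline** — TF-IDF 1–3-grams (min document frequency 2,
  max 0.3·N, stop words excluded) into a one-vs-rest ridge classifier per
  task. Being linear, a prediction decomposes exactly:
  `score_c(x) = Σ_f coef[c,f]·x_f + b_c`, so `coef[c,f]·x_f` is the
  attribution of feature f in one document, and coefficients times the mean
  training input give the classical naive global importance.
* **Segment transformer** — long documents are split into overlapping
  fixed-size subtoken windows; each window is encoded by a small BERT-style
  encoder (implemented in numpy on the package's own autodiff core), segment
  representations are pooled by concatenated average+max pooling with a layer
  norm, and one linear head per task emits class logits. Four attribution
  methods produce per-subtoken scores: attention rollout, Gradient×Activation,
  Integrated Gradients, and epsilon-rule layer-wise relevance propagation.

Subtoken scores are summed per word, words are combined into contiguous
1–3-gram phrases scored by the mean of their word attributions, and negative
records are discarded. For positive phrase attribution W⁺ᵢⱼₜ (sample i,
phrase j, task t), the global aggregates are

```
I_avg(t,j)  = Σᵢ W⁺ᵢⱼₜ / #{i : W⁺ᵢⱼₜ > 0}
I_attr(t,j) = Σᵢ W⁺ᵢⱼₜ
p_tj        = I_attr(t,j) / Σₜ I_attr(t,j)
H_j         = −Σₜ p_tj ln p_tj
I_h(t,j)    = (1 − (H_j − H_min)/(H_max − H_min)) · I_attr(t,j)
```

The homogeneity weight down-ranks phrases whose importance spreads evenly
over tasks, so task-selective phrases rise to the top. Explanations are
evaluated by token removal: masking top-attributed tokens should degrade
macro-F1 faster than masking random tokens (local protocol), and masking
words by a global ranking should drop the ground-truth-class logit
(AOPC, global protocol).

## Worked example

```python
from careinsight import default_config, generate_corpus, split_corpus
from careinsight.bow import fit_bow_on_corpus, bow_global_totals
from careinsight.phrases import homogeneity_from_totals, top_phrases

cfg = default_config(seed=0, n_docs=1000, mean_length=150)
corpus, registry = generate_corpus(cfg)
split = split_corpus([d.doc_id for d in corpus.documents], seed=0)
model, X, _ = fit_bow_on_corpus(corpus, split.train_ids)
scores = homogeneity_from_totals(bow_global_totals(model, X))
top = top_phrases(scores, "m1_mobility", k=5, corpus=corpus)
print(top[["phrase", "i_h", "i_attr", "support", "occurrences"]].round(3)
         .to_string(index=False))
```

prints

```
        phrase   i_h  i_attr  support  occurrences
treppensteigen 4.204   8.804       38           90
      rollator 2.816   5.742       66           92
   sturzgefahr 1.839   4.626       44           61
      transfer 1.469   2.430       45           69
      verkürzt 1.322   3.074       42           73
```

All five top-ranked phrases for the mobility task are (parts of) phrases the
generator planted as mobility signal — `i_h` is the homogeneity-weighted
importance, `support` the number of documents contributing positive
attribution, and `occurrences` the phrase's document frequency in the corpus.

The same tables can be produced end to end from a shell:

```bash
careinsight run-all --seed 0 --out-dir run
```

which generates a corpus, splits it, trains the models, writes global score
TSVs and per-task top-k tables under `run/`, and records every stage seed in
`run/manifest.json`. Individual stages are available as `careinsight
generate | split | train-bow | train-txf | explain | aggregate`.

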