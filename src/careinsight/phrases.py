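"""Phrase construction and global aggregation of local attributions.

Subtoken attributions are merged into word attributions (sum of subtoken
scores per word), words into contiguous 1-3-gram phrases (arithmetic mean of
word scores, stop words excluded), and phrase records into global per-task
rankings.

For positive attribution mass W+_ijt of phrase j in sample i for task t:

    I_avg(t,j)  = Σ_i W+_ijt / #{i : W+_ijt > 0}
    I_attr(t,j) = Σ_i W+_ijt
    p_tj        = I_attr(t,j) / Σ_t I_attr(t,j)
    H_j         = -Σ_t p_tj ln p_tj
    I_h(t,j)    = (1 - (H_j - H_min)/(H_max - H_min)) · I_attr(t,j)

Negative attributions are discarded before aggregation (a negative score for
one task may be a positive one for another); repeated occurrences of a
phrase within one document are summed into a single per-sample record so
that i indexes samples.  The homogeneity weight down-ranks phrases whose
importance spreads evenly over tasks, favoring task-selective phrases.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stopwords import GERMAN_STOP_WORDS

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("doc_id", "task", "phrase", "w_plus")


def merge_subtokens(scores: np.ndarray, word_ids) -> np.ndarray:
    """Sum subtoken attribution scores into per-word scores."""
    scores = np.asarray(scores, dtype=float)
    word_ids = np.asarray(word_ids)
    if scores.shape != word_ids.shape:
        raise ValueError(
            f"score vector ({scores.shape}) inconsistent with word boundaries "
            f"({word_ids.shape})"
        )
    n_words = int(word_ids.max()) + 1 if word_ids.size else 0
    out = np.zeros(n_words)
    np.add.at(out, word_ids, scores)
    return out


def iter_ngrams(words, word_scores, stop_words=GERMAN_STOP_WORDS, max_n: int = 3):
    """Yield ``(phrase, score, position)`` for every eligible 1-3-gram.

    A unigram must not be a stop word; longer n-grams must not consist
    solely of stop words.  The phrase score is the mean of its word scores.
    """
    words = [w.lower() for w in words]
    scores = np.asarray(word_scores, dtype=float)
    for n in range(1, max_n + 1):
        for i in range(len(words) - n + 1):
            gram = words[i : i + n]
            if all(w in stop_words for w in gram):
                continue
            yield " ".join(gram), float(scores[i : i + n].mean()), i


def phrase_records(
    doc_id: str, task: str, words, word_scores, stop_words=GERMAN_STOP_WORDS
) -> pd.DataFrame:
    """Positive phrase-attribution records for one (document, task).

    Occurrence scores are clipped at zero; positive occurrences of the same
    phrase within the document are summed into one record.
    """
    acc: dict[str, float] = {}
    any_gram = False
    for phrase, score, _pos in iter_ngrams(words, word_scores, stop_words):
        any_gram = True
        if score > 0:
            acc[phrase] = acc.get(phrase, 0.0) + score
    if not any_gram:
        logger.warning("document %s empty after stop-word removal", doc_id)
    return pd.DataFrame(
        {
            "doc_id": doc_id,
            "task": task,
            "phrase": list(acc.keys()),
            "w_plus": list(acc.values()),
        },
        columns=list(RECORD_COLUMNS),
    )


def _totals(records: pd.DataFrame) -> pd.DataFrame:
    pos = records[records["w_plus"] > 0]
    if pos.empty:
        return pd.DataFrame(columns=["task", "phrase", "i_attr", "support"])
    g = pos.groupby(["task", "phrase"], sort=False)["w_plus"]
    out = g.agg(i_attr="sum", support="count").reset_index()
    return out


def aggregate_avg(records: pd.DataFrame) -> pd.DataFrame:
    """Global average importance per (task, phrase)."""
    totals = _totals(records)
    totals["i_avg"] = totals["i_attr"] / totals["support"]
    return totals[["task", "phrase", "i_avg", "i_attr", "support"]]


def homogeneity_from_totals(totals: pd.DataFrame) -> pd.DataFrame:
    """Entropy profile and homogeneity-weighted importance from I_attr totals.

    ``totals`` needs columns task, phrase, i_attr, support.  Adds p_tj, H_j
    (natural log, shared across a phrase's rows), the min-max-normalized
    homogeneity weight and I_h.  With a degenerate entropy range (all phrases
    equally homogeneous) the weight is 1 for every phrase.
    """
    if totals.empty:
        return totals.assign(p=[], entropy=[], weight=[], i_h=[], i_avg=[])
    df = totals.copy()
    phrase_mass = df.groupby("phrase")["i_attr"].transform("sum")
    df["p"] = df["i_attr"] / phrase_mass
    plogp = np.where(df["p"] > 0, df["p"] * np.log(df["p"]), 0.0)
    ent = (
        pd.Series(-plogp, index=df.index).groupby(df["phrase"]).transform("sum")
    )
    df["entropy"] = ent
    h_min, h_max = df["entropy"].min(), df["entropy"].max()
    if h_max - h_min < 1e-12:
        df["weight"] = 1.0
    else:
        df["weight"] = 1.0 - (df["entropy"] - h_min) / (h_max - h_min)
    df["i_h"] = df["weight"] * df["i_attr"]
    df["i_avg"] = df["i_attr"] / df["support"]
    return df


def aggregate_homogeneity(records: pd.DataFrame) -> pd.DataFrame:
    """Full homogeneity-weighted aggregation from phrase records."""
    return homogeneity_from_totals(_totals(records))


def corpus_document_frequency(corpus, phrases) -> dict:
    """Document frequency of each phrase (word-boundary matches) in a corpus."""
    texts = [" " + " ".join(d.words) + " " for d in corpus.documents]
    out = {}
    for phrase in phrases:
        needle = " " + phrase + " "
        out[phrase] = sum(1 for t in texts if needle in t)
    return out


def top_phrases(
    scores: pd.DataFrame, task: str, k: int = 20, metric: str = "i_h", corpus=None,
    min_occurrence: int = 0,
) -> pd.DataFrame:
    """Top-k phrases of a task, descending by the chosen metric.

    Ties break by support (descending) then phrase (lexicographic).  With a
    corpus given, each row carries the phrase's corpus document frequency;
    ``min_occurrence`` then filters on it.
    """
    if metric not in ("i_avg", "i_attr", "i_h"):
        raise ValueError(f"unknown metric {metric!r}")
    if task not in set(scores["task"]):
        raise KeyError(f"unknown task {task!r}")
    sub = scores[scores["task"] == task].copy()
    sub = sub.sort_values(
        [metric, "support", "phrase"], ascending=[False, False, True]
    )
    if corpus is not None:
        head = sub.head(max(k * 3, k + 20)) if min_occurrence else sub.head(k)
        occ = corpus_document_frequency(corpus, head["phrase"])
        sub = sub.head(len(head)).assign(occurrences=[occ[p] for p in head["phrase"]])
        if min_occurrence:
            sub = sub[sub["occurrences"] >= min_occurrence]
    return sub.head(k).reset_index(drop=True)


def risk_factor_phrases(
    records: pd.DataFrame, predictions: dict, truths: dict, task: str
) -> dict:
    """Phrases explaining overestimated predictions, per (true, predicted) pair.

    Keeps only samples whose predicted class exceeds the ground truth for
    ``task``, groups them by the (true, predicted) pair and aggregates each
    group with homogeneity weighting.  Returns ``{(true, pred): DataFrame}``
    of the task's ranked phrases; empty when the model never overestimates.
    """
    over = {
        d: (truths[d], predictions[d])
        for d in predictions
        if d in truths and predictions[d] > truths[d]
    }
    if not over:
        logger.info("risk_factor_phrases: no overestimated samples for %s", task)
        return {}
    out = {}
    for pair in sorted(set(over.values())):
        doc_ids = {d for d, tp in over.items() if tp == pair}
        sub = records[records["doc_id"].isin(doc_ids)]
        agg = aggregate_homogeneity(sub)
        if agg.empty or task not in set(agg["task"]):
            out[pair] = agg.iloc[0:0]
            continue
        out[pair] = (
            agg[agg["task"] == task]
            .sort_values(["i_h", "support", "phrase"], ascending=[False, False, True])
            .reset_index(drop=True)
        )
    return out


def planted_recovery_precision(
    scores: pd.DataFrame, registry, task: str, k: int = 20, metric: str = "i_h"
) -> float:
    """Fraction of a task's top-k phrases that touch a planted signal word.

    A hit is a phrase containing at least one word of the task's planted
    exclusive phrases (for the derived care-need task: of any module's).
    """
    signal = registry.signal_words(task)
    top = top_phrases(scores, task, k=k, metric=metric)
    if top.empty:
        return 0.0
    hits = sum(
        1 for p in top["phrase"] if any(w in signal for w in p.split())
    )
    return hits / len(top)
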