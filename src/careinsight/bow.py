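"""TF-IDF 1-3-gram multi-task ridge classifier with linear feature attribution.

The bag-of-words baseline is a one-vs-rest ridge classifier per task over
TF-IDF n-gram features (1-3-grams, minimum document frequency 2, maximum
document frequency 0.3·N).  Because the model is linear, the decision score
of a class decomposes exactly into per-feature contributions:

    score_c(x) = Σ_f coef[c, f] · x_f + intercept_c

``attribute_sample`` returns the per-feature terms of that sum for one
document; ``attribute_naive_global`` multiplies the coefficients with the
mean training input instead, the classical global importance reading of a
sparse linear text classifier.  By linearity the naive global score equals
the mean of the per-sample attributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import RidgeClassifier

from .data_model import Corpus
from .stopwords import GERMAN_STOP_WORDS


@dataclass
class BowFeatureSpace:
    vectorizer: TfidfVectorizer
    vocabulary: list[str]

    def transform(self, texts) -> sp.csr_matrix:
        return self.vectorizer.transform(texts)


def fit_feature_space(
    train_texts,
    min_df: int = 2,
    max_df_fraction: float = 0.3,
    stop_words=GERMAN_STOP_WORDS,
) -> BowFeatureSpace:
    """Fit the TF-IDF 1-3-gram space with document-frequency filtering.

    Raises if the frequency bounds leave an empty vocabulary.
    """
    train_texts = list(train_texts)
    if len(train_texts) < 2:
        raise ValueError("need at least 2 training documents")
    vec = TfidfVectorizer(
        ngram_range=(1, 3),
        min_df=min_df,
        max_df=max_df_fraction,
        stop_words=list(stop_words) if stop_words else None,
        lowercase=True,
        token_pattern=r"(?u)\b\w[\w-]*\b",
        sublinear_tf=False,
        norm="l2",
        smooth_idf=True,
    )
    try:
        vec.fit(train_texts)
    except ValueError as exc:
        raise ValueError(
            "empty vocabulary after document-frequency filtering; "
            "loosen min_df/max_df or provide more documents"
        ) from exc
    return BowFeatureSpace(vectorizer=vec, vocabulary=list(vec.get_feature_names_out()))


@dataclass
class BowTaskModel:
    feature_space: BowFeatureSpace
    classifiers: dict  # task -> fitted RidgeClassifier
    classes: dict  # task -> sorted class labels

    def coef_matrix(self, task: str) -> np.ndarray:
        """Per-class coefficient rows (classes × features), binary expanded."""
        clf = self.classifiers[task]
        coef = np.atleast_2d(clf.coef_)
        if coef.shape[0] == 1:  # binary: sklearn stores the positive-class row
            coef = np.vstack([-coef[0], coef[0]])
        return coef

    def intercepts(self, task: str) -> np.ndarray:
        clf = self.classifiers[task]
        b = np.atleast_1d(clf.intercept_)
        if b.shape[0] == 1 and len(self.classes[task]) == 2:
            b = np.array([-b[0], b[0]])
        return b

    def decision_scores(self, X, task: str) -> np.ndarray:
        """(n_docs × n_classes) decision scores."""
        return X @ self.coef_matrix(task).T + self.intercepts(task)

    def predict(self, X, task: str) -> np.ndarray:
        idx = np.argmax(self.decision_scores(X, task), axis=1)
        return np.asarray(self.classes[task])[idx]

    def predict_all(self, X) -> dict:
        return {t: self.predict(X, t) for t in self.classifiers}


def fit_ridge_multitask(
    feature_space: BowFeatureSpace,
    X: sp.spmatrix,
    labels_per_task: dict,
    alpha: float = 1.0,
) -> BowTaskModel:
    """Fit one independent one-vs-rest ridge classifier per task."""
    classifiers, classes = {}, {}
    for task, y in labels_per_task.items():
        y = np.asarray(y)
        uniq = np.unique(y)
        if uniq.size < 2:
            raise ValueError(f"task {task!r} has a single class in training data")
        clf = RidgeClassifier(alpha=alpha)
        clf.fit(X, y)
        classifiers[task] = clf
        classes[task] = list(clf.classes_)
    return BowTaskModel(feature_space=feature_space, classifiers=classifiers, classes=classes)


def attribute_sample(model: BowTaskModel, x, task: str, cls) -> np.ndarray:
    """Per-feature attribution of one document's decision score.

    ``attribution[f] = coef[cls, f] * tfidf[f]``; summing the vector and
    adding the class intercept reconstructs the decision score exactly.
    """
    ci = model.classes[task].index(cls)
    coef = model.coef_matrix(task)[ci]
    x = np.asarray(x.todense()).ravel() if sp.issparse(x) else np.asarray(x).ravel()
    return coef * x


def attribute_naive_global(model: BowTaskModel, X_train, task: str, cls) -> np.ndarray:
    """Coefficients times the mean training input: the naive global importance."""
    ci = model.classes[task].index(cls)
    coef = model.coef_matrix(task)[ci]
    mean_x = np.asarray(X_train.mean(axis=0)).ravel()
    return coef * mean_x


def fit_bow_on_corpus(
    corpus: Corpus,
    train_ids,
    coarse: bool = True,
    alpha: float = 1.0,
    min_df: int = 2,
    max_df_fraction: float = 0.3,
) -> tuple[BowTaskModel, sp.csr_matrix, list[str]]:
    """Convenience: fit feature space + multitask ridge on a corpus subset.

    Returns the model, the training design matrix and the training id order.
    """
    train = corpus.subset(train_ids)
    texts = [d.text for d in train.documents]
    ids = [d.doc_id for d in train.documents]
    space = fit_feature_space(texts, min_df=min_df, max_df_fraction=max_df_fraction)
    X = space.transform(texts)
    labels = {
        t: train.label_array(t, coarse=coarse) for t in corpus.labels[ids[0]].levels
    }
    model = fit_ridge_multitask(space, X, labels, alpha=alpha)
    return model, X, ids


def bow_global_totals(model: BowTaskModel, X, doc_ids=None, tasks=None):
    """Per-(task, feature) positive attribution totals, fully vectorized.

    For every task, each document is attributed for its *predicted* class
    (coef[class] ⊙ tfidf row), negatives are clipped, and positive mass is
    summed per feature.  Returns a DataFrame with columns task, phrase,
    i_attr, support — the input of homogeneity aggregation — equivalent to
    materializing per-sample phrase records but without the memory blow-up.
    """
    import pandas as pd

    tasks = tasks or list(model.classifiers)
    vocab = np.asarray(model.feature_space.vocabulary)
    frames = []
    for task in tasks:
        preds = model.predict(X, task)
        for ci, cls in enumerate(model.classes[task]):
            rows = np.flatnonzero(preds == cls)
            if rows.size == 0:
                continue
            Xc = X[rows]
            A = Xc.multiply(sp.csr_matrix(model.coef_matrix(task)[ci]))
            A.data = np.maximum(A.data, 0.0)
            A.eliminate_zeros()
            i_attr = np.asarray(A.sum(axis=0)).ravel()
            support = np.asarray((A > 0).sum(axis=0)).ravel()
            keep = support > 0
            frames.append(
                pd.DataFrame(
                    {
                        "task": task,
                        "phrase": vocab[keep],
                        "i_attr": i_attr[keep],
                        "support": support[keep],
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["task", "phrase", "i_attr", "support"])
    out = pd.concat(frames, ignore_index=True)
    # documents of the same task predicted into different classes contribute
    # to the same (task, phrase) pool
    return (
        out.groupby(["task", "phrase"], sort=False, as_index=False)
        .agg(i_attr=("i_attr", "sum"), support=("support", "sum"))
    )


def save_model(model: BowTaskModel, directory) -> None:
    """Persist vocabulary (TSV), coefficients (NPZ) and metadata (JSON)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "vocabulary.tsv", "w", encoding="utf-8") as fh:
        fh.write("\n".join(model.feature_space.vocabulary) + "\n")
    arrays = {"idf": model.feature_space.vectorizer.idf_}
    meta = {"tasks": {}, "params": model.feature_space.vectorizer.get_params(deep=False)}
    meta["params"] = {
        k: v for k, v in meta["params"].items()
        if isinstance(v, (int, float, str, bool, type(None)))
    }
    for task, clf in model.classifiers.items():
        arrays[f"coef_{task}"] = clf.coef_
        arrays[f"intercept_{task}"] = np.atleast_1d(clf.intercept_)
        meta["tasks"][task] = [int(c) for c in model.classes[task]]
    np.savez(directory / "weights.npz", **arrays)
    with open(directory / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
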