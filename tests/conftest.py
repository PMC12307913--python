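"""Shared fixtures: small generated corpora and desk-scale trained models."""

import numpy as np
import pytest

from careinsight import default_config, generate_corpus, split_corpus
from careinsight.bow import fit_bow_on_corpus
from careinsight.tokenize import BpeTokenizer
from careinsight.transformer import SegmentTransformer, TransformerConfig, train_multitask


@pytest.fixture(scope="session")
def small_corpus():
    """400 short documents with the default planted-phrase inventory."""
    cfg = default_config(seed=11, n_docs=400, mean_length=80)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_split(small_corpus):
    corpus, _ = small_corpus
    return split_corpus([d.doc_id for d in corpus.documents], (0.7, 0.15, 0.15), seed=11)


@pytest.fixture(scope="session")
def bow_fit(small_corpus, small_split):
    corpus, _ = small_corpus
    model, X, ids = fit_bow_on_corpus(corpus, small_split.train_ids)
    return model, X, ids


@pytest.fixture(scope="session")
def fixture_model():
    """Tiny 2-layer zero-bias transformer and a single-segment input.

    Zero biases make the relevance-conservation property exactly testable;
    the single segment avoids overlap averaging in stitching.
    """
    tok = BpeTokenizer.train([list("abcdefgh") * 4, ["ab", "cd", "ef", "gh"] * 3],
                             n_merges=12)
    cfg = TransformerConfig(window=16, stride=16, dim=8, heads=2, layers=2,
                            ff_dim=16, seed=7, tasks=("care_need", "m1_mobility"),
                            n_classes=3)
    model = SegmentTransformer(cfg, tok)
    for name, p in model.params.items():
        if name.endswith((".bq", ".bk", ".bv", ".bo", ".b1", ".b2")) or name.endswith(".b") and name.startswith("head."):
            p.data[:] = 0.0
    ids = tok.encode(["ab", "cdef", "gh", "abcd", "ef", "gh"]).ids
    assert len(ids) <= cfg.window
    return model, ids


@pytest.fixture(scope="session")
def late_signal_study():
    """The truncation-ablation study: long documents with signal confined to
    the second half, one segment-pooled and one truncated model trained on
    identical data.  Shared by the faithfulness and architecture tests."""
    cfg = default_config(seed=0, n_docs=500, mean_length=110, signal_position=0.6)
    corpus, registry = generate_corpus(cfg)
    split = split_corpus([d.doc_id for d in corpus.documents], (0.7, 0.15, 0.15), seed=0)
    base = dict(window=64, stride=32, dim=32, heads=2, layers=2, ff_dim=64,
                n_merges=250, epochs=4, lr=2e-3, seed=0)
    pooled, hist_pooled = train_multitask(corpus, split, TransformerConfig(**base))
    truncated, hist_trunc = train_multitask(
        corpus, split, TransformerConfig(truncate=True, **base)
    )
    return {
        "corpus": corpus,
        "registry": registry,
        "split": split,
        "pooled": pooled,
        "truncated": truncated,
        "hist_pooled": hist_pooled,
        "hist_trunc": hist_trunc,
    }
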