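"""Phrase construction and the aggregation formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from careinsight.phrases import (
    aggregate_avg,
    aggregate_homogeneity,
    corpus_document_frequency,
    homogeneity_from_totals,
    iter_ngrams,
    merge_subtokens,
    phrase_records,
    planted_recovery_precision,
    risk_factor_phrases,
    top_phrases,
)

STOPS = frozenset({"der", "die", "und"})


def _records(rows):
    return pd.DataFrame(rows, columns=["doc_id", "task", "phrase", "w_plus"])


class TestMergeSubtokens:
    def test_single_subtoken_word_unchanged(self):
        np.testing.assert_allclose(merge_subtokens([0.7], [0]), [0.7])

    def test_split_word_sums(self):
        out = merge_subtokens([0.2, 0.3, 0.1], [0, 0, 1])
        np.testing.assert_allclose(out, [0.5, 0.1])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(1, 50), st.integers(0, 5))
    def test_matches_bruteforce_grouping(self, n_sub, seed):
        rng = np.random.default_rng(seed)
        word_ids = np.sort(rng.integers(0, max(1, n_sub // 2), size=n_sub))
        word_ids = np.unique(word_ids, return_inverse=True)[1]  # dense 0..k
        scores = rng.normal(size=n_sub)
        got = merge_subtokens(scores, word_ids)
        expected = [scores[word_ids == w].sum() for w in range(word_ids.max() + 1)]
        np.testing.assert_allclose(got, expected)

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            merge_subtokens([0.1, 0.2], [0])


class TestNgramExtraction:
    def test_two_word_example(self):
        grams = dict(
            (p, s) for p, s, _ in iter_ngrams(["a", "b"], [0.6, 0.2], stop_words=STOPS)
        )
        assert grams == {"a": 0.6, "b": 0.2, "a b": pytest.approx(0.4)}

    def test_all_negative_scores_leave_no_records(self):
        recs = phrase_records("d", "care_need", ["a", "b", "c"], [-1.0, -0.5, -0.2],
                              stop_words=STOPS)
        assert recs.empty

    def test_stop_word_rules_match_bruteforce(self):
        words = ["pflege", "der", "rollator", "und", "sturz"]
        scores = [1.0, 2.0, 3.0, 4.0, 5.0]
        got = {(p, round(s, 6)) for p, s, _ in iter_ngrams(words, scores, stop_words=STOPS)}
        expected = set()
        for n in (1, 2, 3):
            for i in range(len(words) - n + 1):
                gram = words[i : i + n]
                if all(w in STOPS for w in gram):
                    continue
                expected.add((" ".join(gram), round(float(np.mean(scores[i : i + n])), 6)))
        assert got == expected

    def test_repeated_phrase_occurrences_summed_per_document(self):
        recs = phrase_records("d", "t", ["x", "y", "x"], [1.0, -3.0, 2.0],
                              stop_words=STOPS)
        row = recs[recs["phrase"] == "x"]
        assert len(row) == 1
        assert row["w_plus"].iloc[0] == pytest.approx(3.0)


class TestAverageAggregation:
    def test_printed_formula(self):
        recs = _records([
            ("d1", "t", "p", 2.0),
            ("d2", "t", "p", 3.0),
            ("d3", "t", "p", 0.0),  # zero sample does not count in the denominator
        ])
        out = aggregate_avg(recs)
        assert out["i_avg"].iloc[0] == pytest.approx(2.5)
        assert out["support"].iloc[0] == 2

    def test_single_sample(self):
        out = aggregate_avg(_records([("d1", "t", "p", 7.0)]))
        assert out["i_avg"].iloc[0] == pytest.approx(7.0)

    def test_all_zero_yields_no_entry(self):
        assert aggregate_avg(_records([("d1", "t", "p", 0.0)])).empty


class TestHomogeneityAggregation:
    def _three_phrase_records(self):
        tasks = [f"t{i}" for i in range(7)]
        rows = [("d1", "t0", "exclusive", 4.0)]
        rows += [(f"d{i}", t, "uniform", 1.0) for i, t in enumerate(tasks)]
        rows += [("d1", "t0", "pair", 1.0), ("d2", "t1", "pair", 1.0)]
        return _records(rows)

    def test_entropy_values(self):
        out = aggregate_homogeneity(self._three_phrase_records())
        by = out.set_index(["phrase", "task"])
        assert by.loc[("exclusive", "t0"), "entropy"] == pytest.approx(0.0, abs=1e-12)
        assert by.loc[("uniform", "t0"), "entropy"] == pytest.approx(np.log(7), abs=1e-12)
        assert by.loc[("pair", "t0"), "entropy"] == pytest.approx(np.log(2), abs=1e-12)

    def test_extreme_weights(self):
        out = aggregate_homogeneity(self._three_phrase_records())
        by = out.set_index(["phrase", "task"])
        # exclusive attains H_min -> weight 1, I_h = I_attr
        assert by.loc[("exclusive", "t0"), "i_h"] == pytest.approx(
            by.loc[("exclusive", "t0"), "i_attr"]
        )
        # uniform attains H_max -> weight 0, I_h = 0
        assert by.loc[("uniform", "t3"), "i_h"] == pytest.approx(0.0, abs=1e-12)

    def test_probability_normalization_and_bounds(self):
        out = aggregate_homogeneity(self._three_phrase_records())
        sums = out.groupby("phrase")["p"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert ((out["weight"] >= 0) & (out["weight"] <= 1)).all()
        assert (out["i_h"] <= out["i_attr"] + 1e-12).all()
        assert ((out["entropy"] >= 0) & (out["entropy"] <= np.log(7) + 1e-12)).all()

    def test_i_avg_times_support_equals_i_attr(self):
        out = aggregate_homogeneity(self._three_phrase_records())
        np.testing.assert_allclose(out["i_avg"] * out["support"], out["i_attr"])

    def test_degenerate_entropy_range_weight_one(self):
        recs = _records([("d1", "t0", "a", 1.0), ("d1", "t0", "b", 2.0)])
        out = aggregate_homogeneity(recs)
        assert (out["weight"] == 1.0).all()
        np.testing.assert_allclose(out["i_h"], out["i_attr"])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 6))
    def test_invariants_on_random_records(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            (f"d{rng.integers(5)}", f"t{rng.integers(4)}", f"p{rng.integers(6)}",
             float(rng.exponential()))
            for _ in range(40)
        ]
        out = aggregate_homogeneity(_records(rows))
        if out.empty:
            return
        np.testing.assert_allclose(out.groupby("phrase")["p"].sum(), 1.0, atol=1e-9)
        assert (out["i_h"] <= out["i_attr"] + 1e-9).all()
        assert (out["entropy"] <= np.log(4) + 1e-9).all()


class TestTopPhrases:
    def _scores(self):
        recs = _records([
            ("d1", "t", "aaa", 3.0), ("d2", "t", "aaa", 3.0),
            ("d1", "t", "bbb", 6.0),
            ("d1", "t", "ccc", 6.0),
        ])
        return aggregate_homogeneity(recs)

    def test_k_larger_than_table(self):
        assert len(top_phrases(self._scores(), "t", k=50)) == 3

    def test_tie_break_lexicographic(self):
        out = top_phrases(self._scores(), "t", k=3, metric="i_attr")
        assert list(out["phrase"]) == ["aaa", "bbb", "ccc"]  # support desc, then lex

    def test_unknown_task_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            top_phrases(self._scores(), "nope", k=5)

    def test_occurrence_counts_attached(self, small_corpus):
        corpus, _ = small_corpus
        df = corpus_document_frequency(corpus, ["rollator", "kein solches wort"])
        assert df["rollator"] > 0
        assert df["kein solches wort"] == 0


class TestRiskFactors:
    def test_perfect_predictions_empty(self):
        recs = _records([("d1", "t", "p", 1.0)])
        assert risk_factor_phrases(recs, {"d1": 1}, {"d1": 1}, "t") == {}

    def test_pair_filter_correctness(self):
        recs = _records([
            ("d1", "t", "overestimated phrase", 5.0),
            ("d2", "t", "correct phrase", 5.0),
            ("d3", "t", "wildly overestimated", 2.0),
        ])
        preds = {"d1": 2, "d2": 1, "d3": 2}
        truths = {"d1": 0, "d2": 1, "d3": 1}
        out = risk_factor_phrases(recs, preds, truths, "t")
        assert set(out) == {(0, 2), (1, 2)}
        assert list(out[(0, 2)]["phrase"]) == ["overestimated phrase"]
        assert list(out[(1, 2)]["phrase"]) == ["wildly overestimated"]

    def test_driving_phrase_ranks_top(self):
        rows = [("d%d" % i, "t", "risiko marker", 4.0) for i in range(5)]
        rows += [("d%d" % i, "t", "beiläufig", 0.5) for i in range(5)]
        preds = {f"d{i}": 2 for i in range(5)}
        truths = {f"d{i}": 0 for i in range(5)}
        out = risk_factor_phrases(_records(rows), preds, truths, "t")
        assert out[(0, 2)]["phrase"].iloc[0] == "risiko marker"


def test_recovery_precision_against_registry(small_corpus):
    _, registry = small_corpus
    signal = sorted(registry.signal_words("m1_mobility"))[:3]
    recs = _records(
        [("d1", "m1_mobility", w, 5.0) for w in signal]
        + [("d1", "m1_mobility", "filler wort", 0.5)]
    )
    scores = aggregate_homogeneity(recs)
    prec = planted_recovery_precision(scores, registry, "m1_mobility", k=3)
    assert prec == 1.0
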