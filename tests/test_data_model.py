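"""Label handling, deterministic splitting and corpus I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from careinsight.data_model import (
    CARE_NEED,
    TASKS,
    Corpus,
    Document,
    TaskLabels,
    coarsen_label,
    read_corpus,
    split_corpus,
    tokenize_words,
    write_corpus,
)


class TestCoarsen:
    @pytest.mark.parametrize(
        "level,task,expected",
        [
            (0, CARE_NEED, 0),
            (2, "m1_mobility", 1),
            (5, CARE_NEED, 2),
            (1, CARE_NEED, 1),
            (3, "m4_selfsuff", 2),
            (4, "m2_cognitive", 2),
        ],
    )
    def test_mapping(self, level, task, expected):
        assert coarsen_label(level, task) == expected

    def test_monotone_and_surjective(self):
        images = [coarsen_label(v, CARE_NEED) for v in range(6)]
        assert images == sorted(images)
        assert set(images) == {0, 1, 2}

    def test_induced_map_on_coarse_values(self):
        # re-coarsening applies the induced map 0->0, 1->1, 2->1 on {0,1,2},
        # so composing twice equals the induced map after one application
        induced = {0: 0, 1: 1, 2: 1}
        for v in range(6):
            c = coarsen_label(v, CARE_NEED)
            assert coarsen_label(c, CARE_NEED) == induced[c]

    def test_out_of_range_names_task_and_value(self):
        with pytest.raises(ValueError, match="m1_mobility"):
            coarsen_label(5, "m1_mobility")
        with pytest.raises(ValueError, match="7"):
            coarsen_label(7, CARE_NEED)


class TestSplit:
    def test_study_sizes(self):
        ids = [str(i) for i in range(72_680)]
        split = split_corpus(ids, (0.70, 0.10, 0.20), seed=0)
        assert split.sizes == (50_876, 7_268, 14_536)

    def test_identity_fractions(self):
        split = split_corpus([str(i) for i in range(10)], (1.0, 0.0, 0.0), seed=1)
        assert split.sizes == (10, 0, 0)

    def test_floor_allocation(self):
        split = split_corpus([str(i) for i in range(10)], (0.70, 0.10, 0.20), seed=1)
        assert split.sizes == (7, 1, 2)

    def test_deterministic(self):
        ids = [f"d{i}" for i in range(137)]
        a = split_corpus(ids, (0.6, 0.2, 0.2), seed=42)
        b = split_corpus(ids, (0.6, 0.2, 0.2), seed=42)
        assert a.train_ids == b.train_ids
        assert a.val_ids == b.val_ids
        assert a.test_ids == b.test_ids

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.integers(1, 300), seed=st.integers(0, 10),
           fr=st.sampled_from([(0.7, 0.1, 0.2), (0.5, 0.25, 0.25), (0.9, 0.05, 0.05)]))
    def test_partition_property(self, n, seed, fr):
        ids = [f"d{i}" for i in range(n)]
        split = split_corpus(ids, fr, seed=seed)
        assert sum(split.sizes) == n
        assert set(split.train_ids) | set(split.val_ids) | set(split.test_ids) == set(ids)
        assert len(split.val_ids) == int(np.floor(n * fr[1]))
        assert len(split.test_ids) == int(np.floor(n * fr[2]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="duplicate"):
            split_corpus(["a", "a"], (0.5, 0.25, 0.25), seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            split_corpus(["a", "b"], (0.5, 0.2, 0.2), seed=0)


def _toy_corpus():
    docs = [
        Document("d1", "Der Rollator steht im Flur"),
        Document("d2", "Kurzzeitgedächtnis lückenhaft, Orientierung fehlend"),
        Document("d3", "Unauffälliger Befund"),
    ]
    labels = {}
    for i, d in enumerate(docs):
        lv = {t: 0 for t in TASKS}
        lv[CARE_NEED] = i % 6
        lv["m1_mobility"] = i % 5
        labels[d.doc_id] = TaskLabels(lv)
    return Corpus(docs, labels)


class TestCorpusIO:
    def test_round_trip(self, tmp_path):
        corpus = _toy_corpus()
        path = tmp_path / "c.jsonl"
        write_corpus(corpus, path)
        back = read_corpus(path)
        assert [d.doc_id for d in back.documents] == [d.doc_id for d in corpus.documents]
        assert [d.text for d in back.documents] == [d.text for d in corpus.documents]
        for d in corpus.documents:
            assert back.labels[d.doc_id].levels == corpus.labels[d.doc_id].levels

    def test_missing_label_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(
            '{"doc_id": "x", "text": "hallo welt", "labels": {"care_need": 1}}\n',
            encoding="utf-8",
        )
        with pytest.raises(ValueError, match="line 1"):
            read_corpus(path)

    def test_malformed_line_names_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        good = '{"doc_id": "x", "text": "hallo", "labels": {%s}}' % ", ".join(
            f'"{t}": 0' for t in TASKS
        )
        path.write_text(good + "\nnot json\n", encoding="utf-8")
        with pytest.raises(ValueError, match="line 2"):
            read_corpus(path)

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "empty.jsonl"
        path.write_text("", encoding="utf-8")
        with caplog.at_level("WARNING"):
            corpus = read_corpus(path)
        assert len(corpus) == 0
        assert any("no records" in r.message for r in caplog.records)


def test_tokenizer_reconstructs_words():
    text = "Der Patient benutzt einen Rollator, Treppen-steigen unmöglich!"
    words = tokenize_words(text)
    assert words == ["der", "patient", "benutzt", "einen", "rollator",
                     "treppen-steigen", "unmöglich"]
    doc = Document("d", text)
    assert doc.words == words and doc.length == len(words)
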