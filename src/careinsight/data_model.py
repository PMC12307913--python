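"""Core data types for care-need assessment corpora.

A corpus is a set of documents (free-text assessment notes), each carrying
ordinal labels for seven prediction tasks: the overall care-need level (0-5)
and six module levels (0-4) covering areas of daily life (mobility, cognitive
and communication skills, behavioral problems, self-sufficiency, self-therapy,
everyday life).  A coarse three-class view (0 -> 0; 1,2 -> 1; 3,4,5 -> 2) is
used for all explanation experiments.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

CARE_NEED = "care_need"
MODULE_TASKS = (
    "m1_mobility",
    "m2_cognitive",
    "m3_behavioral",
    "m4_selfsuff",
    "m5_selftherapy",
    "m6_everyday",
)
TASKS = (CARE_NEED,) + MODULE_TASKS

#: inclusive upper bound of the full label range per task
FULL_RANGE = {t: (5 if t == CARE_NEED else 4) for t in TASKS}
N_COARSE_CLASSES = 3

_WORD_RE = re.compile(r"[0-9a-zA-ZäöüÄÖÜßà-ÿÀ-ß]+(?:-[0-9a-zA-ZäöüÄÖÜßà-ÿÀ-ß]+)*")


def tokenize_words(text: str) -> list[str]:
    """Split text into lowercased word tokens.

    Splits on whitespace and strips punctuation, keeping intra-word hyphens
    (German compounds such as "an-" and "auskleiden" variants survive).
    """
    return [w.lower() for w in _WORD_RE.findall(text)]


def coarsen_label(level: int, task: str) -> int:
    """Map a full ordinal label onto the coarse 3-class scheme.

    The mapping is 0 -> 0; 1,2 -> 1; 3,4,5 -> 2 for every task (modules only
    reach 4, so class 2 covers {3,4} there).
    """
    if task not in FULL_RANGE:
        raise KeyError(f"unknown task {task!r}")
    hi = FULL_RANGE[task]
    if not (isinstance(level, (int, np.integer)) and 0 <= level <= hi):
        raise ValueError(
            f"label {level!r} out of range 0..{hi} for task {task!r}"
        )
    if level == 0:
        return 0
    return 1 if level <= 2 else 2


@dataclass
class Document:
    """One assessment-like text with a stable identifier."""

    doc_id: str
    text: str
    words: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.words:
            self.words = tokenize_words(self.text)
        if len(self.words) < 1:
            raise ValueError(f"document {self.doc_id!r} has no words")

    @property
    def length(self) -> int:
        return len(self.words)


@dataclass
class TaskLabels:
    """Ordinal labels for the seven tasks of one document."""

    levels: dict[str, int]

    def __post_init__(self) -> None:
        for task in TASKS:
            if task not in self.levels:
                raise ValueError(f"missing label for task {task!r}")
            coarsen_label(self.levels[task], task)  # range check

    def coarse(self) -> dict[str, int]:
        return {t: coarsen_label(v, t) for t, v in self.levels.items()}

    def __getitem__(self, task: str) -> int:
        return self.levels[task]


@dataclass
class Corpus:
    documents: list[Document]
    labels: dict[str, TaskLabels]

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate doc_id in corpus")
        missing = set(ids) - set(self.labels)
        if missing:
            raise ValueError(f"documents without labels: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def subset(self, doc_ids) -> "Corpus":
        wanted = set(doc_ids)
        docs = [d for d in self.documents if d.doc_id in wanted]
        return Corpus(docs, {d.doc_id: self.labels[d.doc_id] for d in docs})

    def label_array(self, task: str, coarse: bool = True) -> np.ndarray:
        if coarse:
            return np.array(
                [self.labels[d.doc_id].coarse()[task] for d in self.documents]
            )
        return np.array([self.labels[d.doc_id][task] for d in self.documents])


@dataclass
class CorpusSplit:
    """Disjoint train/validation/test id sets covering a corpus."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split sets are not pairwise disjoint")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_ids), len(self.val_ids), len(self.test_ids))


def split_corpus(doc_ids, fractions=(0.70, 0.10, 0.20), seed: int = 0) -> CorpusSplit:
    """Deterministically partition ids into train/validation/test.

    Validation and test receive ``floor(N * fraction)`` ids each; the training
    set absorbs the remainder, so 72,680 ids at 0.70/0.10/0.20 give exactly
    50,876 / 7,268 / 14,536.  Ids are shuffled by ``seed`` before allocation.
    """
    doc_ids = list(doc_ids)
    if len(set(doc_ids)) != len(doc_ids):
        raise ValueError("duplicate ids passed to split_corpus")
    f_train, f_val, f_test = fractions
    if min(fractions) < 0 or abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError(f"fractions must be non-negative and sum to 1, got {fractions}")
    n = len(doc_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [doc_ids[i] for i in order]
    n_val = int(np.floor(n * f_val))
    n_test = int(np.floor(n * f_test))
    n_train = n - n_val - n_test
    return CorpusSplit(
        train_ids=shuffled[:n_train],
        val_ids=shuffled[n_train : n_train + n_val],
        test_ids=shuffled[n_train + n_val :],
    )


def write_corpus(corpus: Corpus, path) -> None:
    """Write a corpus as JSONL, one ``{doc_id, text, labels}`` record per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            rec = {
                "doc_id": doc.doc_id,
                "text": doc.text,
                "labels": dict(corpus.labels[doc.doc_id].levels),
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_corpus(path) -> Corpus:
    """Read a JSONL corpus written by :func:`write_corpus`.

    Malformed lines and missing label fields are rejected with the line number.
    """
    documents: list[Document] = []
    labels: dict[str, TaskLabels] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            try:
                doc = Document(doc_id=str(rec["doc_id"]), text=rec["text"])
                labels[doc.doc_id] = TaskLabels({t: int(v) for t, v in rec["labels"].items()})
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: invalid record on line {lineno}: {exc}") from exc
            documents.append(doc)
    if not documents:
        logger.warning("read_corpus: %s contained no records", path)
    return Corpus(documents, labels)


def write_id_list(ids, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(ids) + ("\n" if ids else ""))


def read_id_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]
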