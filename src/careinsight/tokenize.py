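"""Byte-pair-encoding subtokenizer with word-boundary tracking.

The transformer consumes subword units learned from the training split; a word
may split into several subtokens that must later be merged back (their
attribution scores are summed) before phrase construction.  The encoder keeps
an explicit subtoken -> word index map so merging is exact.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

PAD, MASK, UNK = "<pad>", "<mask>", "<unk>"
SPECIALS = (PAD, MASK, UNK)
PAD_ID, MASK_ID, UNK_ID = 0, 1, 2


@dataclass
class Encoding:
    """Subtoken ids for a word sequence plus the word index of each subtoken."""

    ids: list[int]
    word_ids: list[int]
    pieces: list[str]

    def __len__(self) -> int:
        return len(self.ids)


class BpeTokenizer:
    """Greedy byte-pair encoding over word types.

    Merges are learned from word frequencies: the most frequent adjacent
    symbol pair is merged repeatedly until ``n_merges`` merges are recorded or
    no pair occurs at least twice.  Encoding replays merges in learned order.
    """

    def __init__(self, merges=None, alphabet=None):
        self.merges: list[tuple[str, str]] = list(merges or [])
        self.alphabet: list[str] = list(alphabet or [])
        self._rebuild()

    def _rebuild(self) -> None:
        self.vocab: list[str] = list(SPECIALS) + self.alphabet + [
            a + b for a, b in self.merges
        ]
        self.token_to_id = {tok: i for i, tok in enumerate(self.vocab)}
        self._merge_rank = {pair: r for r, pair in enumerate(self.merges)}
        self._cache: dict[str, list[str]] = {}

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @classmethod
    def train(cls, word_lists, n_merges: int = 300) -> "BpeTokenizer":
        """Learn merges from an iterable of word sequences (one per document)."""
        freqs = Counter()
        for words in word_lists:
            freqs.update(words)
        alphabet = sorted({ch for w in freqs for ch in w})
        symbolized = {w: tuple(w) for w in freqs}
        merges: list[tuple[str, str]] = []
        for _ in range(n_merges):
            pair_counts = Counter()
            for w, syms in symbolized.items():
                f = freqs[w]
                for i in range(len(syms) - 1):
                    pair_counts[(syms[i], syms[i + 1])] += f
            if not pair_counts:
                break
            # deterministic tie-break: count desc, then lexicographic
            (a, b), count = min(
                pair_counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
            if count < 2:
                break
            merges.append((a, b))
            merged = a + b
            for w, syms in symbolized.items():
                out, i = [], 0
                while i < len(syms):
                    if i + 1 < len(syms) and syms[i] == a and syms[i + 1] == b:
                        out.append(merged)
                        i += 2
                    else:
                        out.append(syms[i])
                        i += 1
                symbolized[w] = tuple(out)
        return cls(merges=merges, alphabet=alphabet)

    def encode_word(self, word: str) -> list[str]:
        cached = self._cache.get(word)
        if cached is not None:
            return cached
        syms = [ch if ch in self.token_to_id else UNK for ch in word]
        while len(syms) > 1:
            best, best_rank = None, None
            for i in range(len(syms) - 1):
                rank = self._merge_rank.get((syms[i], syms[i + 1]))
                if rank is not None and (best_rank is None or rank < best_rank):
                    best, best_rank = i, rank
            if best is None:
                break
            syms[best : best + 2] = [syms[best] + syms[best + 1]]
        self._cache[word] = syms
        return syms

    def encode(self, words) -> Encoding:
        ids, word_ids, pieces = [], [], []
        for wi, word in enumerate(words):
            for piece in self.encode_word(word):
                ids.append(self.token_to_id.get(piece, UNK_ID))
                word_ids.append(wi)
                pieces.append(piece)
        return Encoding(ids=ids, word_ids=word_ids, pieces=pieces)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"alphabet": self.alphabet, "merges": self.merges}, fh)

    @classmethod
    def load(cls, path) -> "BpeTokenizer":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(
            merges=[tuple(m) for m in data["merges"]], alphabet=data["alphabet"]
        )
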