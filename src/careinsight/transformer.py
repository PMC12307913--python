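"""Long-document multi-task transformer classifier.

Documents longer than the encoder window are split into overlapping
fixed-size subtoken segments; each segment is encoded independently by a
small BERT-style encoder, segment representations are combined by
concatenated average- and max-pooling followed by a layer norm, and one
linear head per task produces class logits.  A truncation variant (first
segment only) is available for ablation; on long documents whose signal sits
in late segments it underperforms the pooled model.

The encoder is implemented on the package's own autodiff core (``nn``), so
gradients with respect to the input embeddings — needed by the attribution
methods — are available directly, and every forward pass can record the
intermediate activations the relevance-propagation explainer consumes.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .data_model import CARE_NEED, N_COARSE_CLASSES, TASKS, Corpus
from .tokenize import BpeTokenizer, Encoding, MASK_ID, PAD_ID
from .faithfulness import macro_f1


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TransformerConfig:
    window: int = 512
    stride: int | None = None  # default window // 2
    dim: int = 64
    heads: int = 2
    layers: int = 2
    ff_dim: int = 128
    n_merges: int = 300
    tasks: tuple = TASKS
    n_classes: int = N_COARSE_CLASSES
    truncate: bool = False
    lr: float = 1e-3
    epochs: int = 6
    #: fraction of training subtokens replaced by the mask token each epoch
    #: (BERT-style masking noise); keeps the mask token in-distribution so
    #: that token-removal evaluation probes the model rather than an
    #: out-of-distribution artifact
    mask_prob: float = 0.1
    seed: int = 0

    @property
    def effective_stride(self) -> int:
        return self.stride if self.stride is not None else max(1, self.window // 2)


def segment_starts(n_subtokens: int, window: int, stride: int) -> list[int]:
    """Start offsets of overlapping segments covering all positions."""
    if not 1 <= stride <= window:
        raise ValueError(f"stride must be in [1, window], got {stride} > {window}")
    if n_subtokens <= window:
        return [0]
    starts = list(range(0, n_subtokens - window + 1, stride))
    if starts[-1] + window < n_subtokens:
        starts.append(n_subtokens - window)
    return starts


def segment(ids, window: int, stride: int):
    """Split subtoken ids into padded segments.

    Returns ``(seg_ids (S, window) int, mask (S, window) float, starts)``.
    The inverse mapping is implicit: document position p is held by every
    segment s with ``starts[s] <= p < starts[s] + window`` at offset
    ``p - starts[s]``.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("cannot segment an empty subtoken sequence")
    starts = segment_starts(len(ids), window, stride)
    seg_ids = np.full((len(starts), window), PAD_ID, dtype=np.int64)
    mask = np.zeros((len(starts), window), dtype=np.float64)
    for s, st in enumerate(starts):
        chunk = ids[st : st + window]
        seg_ids[s, : len(chunk)] = chunk
        mask[s, : len(chunk)] = 1.0
    return seg_ids, mask, starts


def stitch_segments(per_segment: np.ndarray, starts, n_subtokens: int) -> np.ndarray:
    """Merge per-segment position scores into one document-level vector.

    Positions covered by several overlapping segments receive the mean of
    their per-segment scores; padding positions are dropped.
    """
    total = np.zeros(n_subtokens)
    count = np.zeros(n_subtokens)
    window = per_segment.shape[1]
    for s, st in enumerate(starts):
        hi = min(st + window, n_subtokens)
        total[st:hi] += per_segment[s, : hi - st]
        count[st:hi] += 1
    if np.any(count == 0):
        raise ValueError("segmentation does not cover every position")
    return total / count


def _init_params(cfg: TransformerConfig, vocab_size: int) -> dict:
    rng = np.random.default_rng(cfg.seed)
    d, f = cfg.dim, cfg.ff_dim

    def w(*shape, scale=0.02):
        return nn.Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

    def zeros(*shape):
        return nn.Tensor(np.zeros(shape), requires_grad=True)

    def ones(*shape):
        return nn.Tensor(np.ones(shape), requires_grad=True)

    p = {"tok_emb": w(vocab_size, d), "pos_emb": w(cfg.window, d)}
    for l in range(cfg.layers):
        p[f"l{l}.Wq"], p[f"l{l}.bq"] = w(d, d), zeros(d)
        p[f"l{l}.Wk"], p[f"l{l}.bk"] = w(d, d), zeros(d)
        p[f"l{l}.Wv"], p[f"l{l}.bv"] = w(d, d), zeros(d)
        p[f"l{l}.Wo"], p[f"l{l}.bo"] = w(d, d), zeros(d)
        p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"] = ones(d), zeros(d)
        p[f"l{l}.W1"], p[f"l{l}.b1"] = w(d, f), zeros(f)
        p[f"l{l}.W2"], p[f"l{l}.b2"] = w(f, d), zeros(d)
        p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"] = ones(d), zeros(d)
    p["pool_ln.g"], p["pool_ln.b"] = ones(2 * d), zeros(2 * d)
    for task in cfg.tasks:
        p[f"head.{task}.W"] = w(2 * d, cfg.n_classes)
        p[f"head.{task}.b"] = zeros(cfg.n_classes)
    return p


class SegmentTransformer:
    """Encoder + segment pooling + per-task linear heads."""

    def __init__(self, cfg: TransformerConfig, tokenizer: BpeTokenizer, params=None):
        self.cfg = cfg
        self.tokenizer = tokenizer
        self.params = params or _init_params(cfg, tokenizer.vocab_size)

    # -- forward ------------------------------------------------------------
    def embed(self, seg_ids: np.ndarray) -> nn.Tensor:
        window = seg_ids.shape[1]
        return nn.gather(self.params["tok_emb"], seg_ids) + nn.gather(
            self.params["pos_emb"], np.arange(window)
        )

    def forward(self, ids, cache: dict | None = None, X0: nn.Tensor | None = None):
        """Run the full model on one document's subtoken ids.

        Returns ``(logits: {task: Tensor (C,)}, X0, (seg_ids, mask, starts))``.
        ``X0`` may be supplied directly (path inputs for integrated
        gradients); ``cache`` collects intermediate activations for LRP and
        attention rollout.
        """
        cfg = self.cfg
        stride = cfg.window if cfg.truncate else cfg.effective_stride
        seg_ids, mask, starts = segment(ids, cfg.window, stride)
        if cfg.truncate:
            seg_ids, mask, starts = seg_ids[:1], mask[:1], starts[:1]
        if X0 is None:
            X0 = self.embed(seg_ids)
        logits = self._encode(X0, mask, cache)
        return logits, X0, (seg_ids, mask, starts)

    def _encode(self, X0: nn.Tensor, mask: np.ndarray, cache: dict | None):
        p, cfg = self.params, self.cfg
        S, W = mask.shape
        d, H = cfg.dim, cfg.heads
        dh = d // H
        attn_bias = (1.0 - mask)[:, None, None, :] * -1e9
        if cache is not None:
            cache["mask"] = mask.copy()
            cache["X0"] = X0.data.copy()
            cache["layers"] = []
        x = X0
        for l in range(cfg.layers):
            x_in = x

            def heads(t):
                return t.reshape(S, W, H, dh).transpose((0, 2, 1, 3))

            q = heads(x @ p[f"l{l}.Wq"] + p[f"l{l}.bq"])
            k = heads(x @ p[f"l{l}.Wk"] + p[f"l{l}.bk"])
            v = heads(x @ p[f"l{l}.Wv"] + p[f"l{l}.bv"])
            scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(dh)) + attn_bias
            A = nn.softmax(scores, axis=-1)
            ctx = (A @ v).transpose((0, 2, 1, 3)).reshape(S, W, d)
            attn_out = ctx @ p[f"l{l}.Wo"] + p[f"l{l}.bo"]
            res1 = x_in + attn_out
            ln1 = nn.layer_norm(res1, p[f"l{l}.ln1.g"], p[f"l{l}.ln1.b"])
            h_pre = ln1 @ p[f"l{l}.W1"] + p[f"l{l}.b1"]
            h = nn.gelu(h_pre)
            ffn_out = h @ p[f"l{l}.W2"] + p[f"l{l}.b2"]
            res2 = ln1 + ffn_out
            x = nn.layer_norm(res2, p[f"l{l}.ln2.g"], p[f"l{l}.ln2.b"])
            if cache is not None:
                cache["layers"].append(
                    {
                        "x_in": x_in.data.copy(),
                        "A": A.data.copy(),
                        "v": v.data.copy(),
                        "ctx": ctx.data.copy(),
                        "attn_out": attn_out.data.copy(),
                        "res1": res1.data.copy(),
                        "ln1": ln1.data.copy(),
                        "h": h.data.copy(),
                        "ffn_out": ffn_out.data.copy(),
                        "res2": res2.data.copy(),
                        "out": x.data.copy(),
                    }
                )

        counts = mask.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError("all-padding segment")
        m3 = mask[:, :, None]
        seg_rep = (x * m3).sum(axis=1) * (1.0 / counts)[:, None]
        doc_mean = seg_rep.mean(axis=0)
        doc_max = seg_rep.max(axis=0)
        pooled = nn.concat([doc_mean, doc_max], axis=-1)
        rep = nn.layer_norm(pooled, p["pool_ln.g"], p["pool_ln.b"])
        logits = {
            t: rep @ p[f"head.{t}.W"] + p[f"head.{t}.b"] for t in cfg.tasks
        }
        if cache is not None:
            cache["x_final"] = x.data.copy()
            cache["counts"] = counts.copy()
            cache["seg_rep"] = seg_rep.data.copy()
            cache["max_arg"] = np.argmax(seg_rep.data, axis=0)
            cache["pooled"] = pooled.data.copy()
            cache["rep"] = rep.data.copy()
            cache["logits"] = {t: lg.data.copy() for t, lg in logits.items()}
        return logits

    def pool_segment_reps(self, seg_reps: np.ndarray) -> np.ndarray:
        """Pool pre-computed segment representations (order-invariant)."""
        pooled = np.concatenate([seg_reps.mean(axis=0), seg_reps.max(axis=0)])
        g, b = self.params["pool_ln.g"].data, self.params["pool_ln.b"].data
        mu, var = pooled.mean(), pooled.var()
        return (pooled - mu) / np.sqrt(var + 1e-5) * g + b

    # -- inference ----------------------------------------------------------
    def encode_doc(self, words) -> Encoding:
        return self.tokenizer.encode(words)

    def predict_doc(self, ids):
        logits, _, _ = self.forward(ids)
        lg = {t: v.data.copy() for t, v in logits.items()}
        preds = {t: int(np.argmax(v)) for t, v in lg.items()}
        return preds, lg

    # -- persistence --------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "config.json", "w", encoding="utf-8") as fh:
            json.dump(asdict(self.cfg), fh, indent=2)
        self.tokenizer.save(directory / "tokenizer.json")
        np.savez(directory / "weights.npz", **{k: p.data for k, p in self.params.items()})

    @classmethod
    def load(cls, directory) -> "SegmentTransformer":
        directory = Path(directory)
        with open(directory / "config.json", encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["tasks"] = tuple(raw["tasks"])
        cfg = TransformerConfig(**raw)
        tok = BpeTokenizer.load(directory / "tokenizer.json")
        weights = np.load(directory / "weights.npz")
        params = {k: nn.Tensor(weights[k], requires_grad=True) for k in weights.files}
        return cls(cfg, tok, params=params)


@dataclass
class TrainingHistory:
    epochs: list = field(default_factory=list)  # (epoch, train_loss, val_f1)
    best_epoch: int = -1
    best_val_f1: float = -1.0


def train_multitask(
    corpus: Corpus,
    split,
    cfg: TransformerConfig,
    tokenizer: BpeTokenizer | None = None,
) -> tuple[SegmentTransformer, TrainingHistory]:
    """Joint training with summed per-task cross-entropy.

    The subtokenizer is learned on the training split unless provided.  Model
    selection is on validation care-need macro-F1; training aborts with
    diagnostics if the loss becomes non-finite.
    """
    train = corpus.subset(split.train_ids)
    val = corpus.subset(split.val_ids)
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation splits must be non-empty")
    if tokenizer is None:
        tokenizer = BpeTokenizer.train(
            (d.words for d in train.documents), n_merges=cfg.n_merges
        )
    model = SegmentTransformer(cfg, tokenizer)
    opt = nn.Adam({k: p for k, p in model.params.items()}, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)

    enc_train = [tokenizer.encode(d.words).ids for d in train.documents]
    enc_val = [tokenizer.encode(d.words).ids for d in val.documents]
    y_train = {t: train.label_array(t, coarse=cfg.n_classes == N_COARSE_CLASSES)
               for t in cfg.tasks}
    y_val = val.label_array(CARE_NEED, coarse=cfg.n_classes == N_COARSE_CLASSES)

    history = TrainingHistory()
    best_params = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(enc_train))
        total_loss = 0.0
        for i in order:
            opt.zero_grad()
            ids = enc_train[int(i)]
            if cfg.mask_prob > 0:
                ids = np.asarray(ids).copy()
                ids[rng.random(len(ids)) < cfg.mask_prob] = MASK_ID
                ids = list(ids)
            logits, _, _ = model.forward(ids)
            loss = None
            for t in cfg.tasks:
                ll = -nn.pick(nn.log_softmax(logits[t]), int(y_train[t][int(i)]))
                loss = ll if loss is None else loss + ll
            lv = float(loss.data)
            if not np.isfinite(lv) or lv > 1e8:
                raise TrainingDiverged(
                    f"diverged loss {lv} at epoch {epoch}, doc index {int(i)}"
                )
            total_loss += lv
            loss.backward()
            opt.step()
        preds = [int(np.argmax(model.forward(ids)[0][CARE_NEED].data)) for ids in enc_val]
        val_f1 = macro_f1(preds, y_val, classes=range(cfg.n_classes))
        history.epochs.append((epoch, total_loss / max(1, len(enc_train)), val_f1))
        if val_f1 > history.best_val_f1:
            history.best_val_f1 = val_f1
            history.best_epoch = epoch
            best_params = {k: p.data.copy() for k, p in model.params.items()}
    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
    return model, history


def predict_corpus(model: SegmentTransformer, corpus: Corpus, doc_ids, task: str):
    """Predicted classes for ``task`` over a corpus subset, in id order."""
    sub = corpus.subset(doc_ids)
    preds = []
    for doc in sub.documents:
        ids = model.encode_doc(doc.words).ids
        p, _ = model.predict_doc(ids)
        preds.append(p[task])
    return [d.doc_id for d in sub.documents], np.array(preds)
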