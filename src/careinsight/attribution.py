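"""Per-subtoken feature attribution for the segment transformer.

Four methods are provided, all emitting the same :class:`TokenAttributionMap`
shape so downstream phrase aggregation is explainer-independent:

* **attention** — attention-rollout: per layer, head-averaged attention mixed
  with the identity (residual weight 0.5) and row-normalized, composed across
  layers by matrix product.  Task- and class-agnostic, non-negative.
* **lgxa** — Gradient × Activation: the gradient of the explained class logit
  with respect to the input embeddings, multiplied elementwise by the
  embeddings and summed over the embedding dimension (signed).
* **ig** — Integrated Gradients: a Riemann (midpoint) approximation of the
  path integral of gradients from a baseline (padding-token embeddings or
  zeros) to the input, times the input-minus-baseline difference.  Satisfies
  completeness: attributions sum to logit(input) − logit(baseline) up to the
  discretization error of the path integral.
* **lrp** — epsilon-rule layer-wise relevance propagation: the explained
  logit is redistributed backwards layer by layer.  Linear layers use the
  epsilon rule; residual sums split relevance proportionally to the two
  summands; attention weights and layer norms are treated as constant mixing
  (relevance passes through attention as through a fixed matrix, and through
  layer norm unchanged).  Conservation is exact up to epsilon slack and bias
  absorption.

Scores are stitched across overlapping segments by averaging at shared
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .tokenize import PAD_ID
from .transformer import SegmentTransformer, stitch_segments


@dataclass
class TokenAttributionMap:
    doc_id: str | None
    task: str | None
    explained_class: int | None
    method: str
    scores: np.ndarray  # one real per document subtoken

    def __len__(self) -> int:
        return len(self.scores)


def _stitch_masked(per_seg: np.ndarray, mask: np.ndarray, starts, n: int) -> np.ndarray:
    # padding positions never overlap real positions (padding only occurs at
    # the document tail of the last segment), so plain stitching suffices
    return stitch_segments(per_seg, starts, n)


def attention_rollout(attentions, mask: np.ndarray) -> np.ndarray:
    """Compose per-layer attention maps into per-position importance.

    ``attentions`` is one ``(S, H, W, W)`` array per layer (softmax rows).
    Heads are averaged, the identity is mixed in with residual weight 0.5,
    rows are renormalized, and layers are composed by matrix product.  The
    importance of input position j is the mean attention it receives from
    the valid query positions of its segment.
    """
    S, W = mask.shape
    rollout = np.repeat(np.eye(W)[None], S, axis=0)
    for A in attentions:
        A = A.mean(axis=1)  # heads averaged -> (S, W, W)
        A = 0.5 * A + 0.5 * np.eye(W)[None]
        A = A / A.sum(axis=-1, keepdims=True)
        rollout = A @ rollout
    valid = mask[:, :, None]
    per_seg = (rollout * valid).sum(axis=1) / np.maximum(valid.sum(axis=1), 1.0)
    return per_seg * mask


def attention_attribution(model: SegmentTransformer, ids, doc_id=None) -> TokenAttributionMap:
    """Attention-rollout token importance (one map per document)."""
    cache: dict = {}
    model.forward(ids, cache=cache)
    if not cache.get("layers"):
        raise ValueError("model recorded no attention weights")
    mask = cache["mask"]
    per_seg = attention_rollout([layer["A"] for layer in cache["layers"]], mask)
    scores = _stitch_masked(per_seg, mask, cache_starts(model, ids), len(ids))
    return TokenAttributionMap(doc_id, None, None, "attention", scores)


def cache_starts(model: SegmentTransformer, ids) -> list[int]:
    from .transformer import segment

    stride = model.cfg.window if model.cfg.truncate else model.cfg.effective_stride
    _, _, starts = segment(ids, model.cfg.window, stride)
    return starts if not model.cfg.truncate else starts[:1]


def gradient_x_activation(
    model: SegmentTransformer, ids, task: str, cls: int, doc_id=None
) -> TokenAttributionMap:
    """Embedding activation times the gradient of the class logit."""
    logits, X0, (seg_ids, mask, starts) = model.forward(ids)
    nn.pick(logits[task], cls).backward()
    if X0.grad is None or not np.all(np.isfinite(X0.grad)):
        raise FloatingPointError("non-finite gradients in gradient_x_activation")
    per_seg = (X0.grad * X0.data).sum(axis=-1) * mask
    scores = _stitch_masked(per_seg, mask, starts, len(ids))
    return TokenAttributionMap(doc_id, task, cls, "lgxa", scores)


def integrated_gradients(
    model: SegmentTransformer,
    ids,
    task: str,
    cls: int,
    steps: int = 64,
    baseline: str = "pad",
    doc_id=None,
    return_completeness: bool = False,
):
    """Path-integral attribution from a neutral baseline to the input."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    logits_x, X0, (seg_ids, mask, starts) = model.forward(ids)
    x = X0.data
    if baseline == "zero":
        b = np.zeros_like(x)
    elif baseline == "pad":
        b = model.embed(np.full_like(seg_ids, PAD_ID)).data
    else:
        raise ValueError("baseline must be 'pad' or 'zero'")
    diff = x - b
    grad_acc = np.zeros_like(x)
    for s in range(steps):
        alpha = (s + 0.5) / steps
        Xa = nn.Tensor(b + alpha * diff, requires_grad=True)
        logits = model._encode(Xa, mask, None)
        nn.pick(logits[task], cls).backward()
        if Xa.grad is None or not np.all(np.isfinite(Xa.grad)):
            raise FloatingPointError("non-finite partials in integrated_gradients")
        grad_acc += Xa.grad
    attr = diff * grad_acc / steps
    per_seg = attr.sum(axis=-1) * mask
    scores = _stitch_masked(per_seg, mask, starts, len(ids))
    amap = TokenAttributionMap(doc_id, task, cls, "ig", scores)
    if return_completeness:
        logits_b = model._encode(nn.Tensor(b), mask, None)
        delta = float(logits_x[task].data[cls] - logits_b[task].data[cls])
        return amap, float(attr.sum()), delta
    return amap


def _eps_div(R: np.ndarray, z: np.ndarray, eps: float) -> np.ndarray:
    stab = z + eps * np.sign(z)
    stab = np.where(stab == 0.0, eps, stab)
    return R / stab


def _lrp_linear(x: np.ndarray, W: np.ndarray, z: np.ndarray, R: np.ndarray, eps: float):
    """Epsilon-rule relevance through ``z = x @ W (+ b)``."""
    s = _eps_div(R, z, eps)
    return x * (s @ W.T)


def lrp(
    model: SegmentTransformer,
    ids,
    task: str,
    cls: int,
    eps: float = 1e-6,
    doc_id=None,
    return_conservation: bool = False,
):
    """Epsilon-LRP relevance of the explained class logit per subtoken."""
    cache: dict = {}
    logits, _, (seg_ids, mask, starts) = model.forward(ids, cache=cache)
    p = {k: t.data for k, t in model.params.items()}
    cfg = model.cfg
    S, W = mask.shape
    d, H = cfg.dim, cfg.heads
    dh = d // H

    logit = cache["logits"][task]
    R_logits = np.zeros_like(logit)
    R_logits[cls] = logit[cls]
    R_rep = _lrp_linear(cache["rep"], p[f"head.{task}.W"], logit, R_logits, eps)
    # pooling layer norm: constant mixing, relevance passes through
    R_mean, R_max = R_rep[:d], R_rep[d:]
    seg_rep = cache["seg_rep"]
    doc_mean = seg_rep.mean(axis=0)
    R_seg = (seg_rep / S) * _eps_div(R_mean, doc_mean, eps)[None, :]
    R_seg[cache["max_arg"], np.arange(d)] += R_max
    # segment representation: masked mean over positions
    x_final = cache["x_final"]
    contrib = x_final * mask[:, :, None] / cache["counts"][:, None, None]
    R_x = contrib * _eps_div(R_seg, seg_rep, eps)[:, None, :]

    for l in reversed(range(cfg.layers)):
        layer = cache["layers"][l]
        # output layer norm: pass through
        R_res2 = R_x
        ln1, ffn_out, res2 = layer["ln1"], layer["ffn_out"], layer["res2"]
        s2 = _eps_div(R_res2, res2, eps)
        R_ln1_res, R_ffn = ln1 * s2, ffn_out * s2
        R_h = _lrp_linear(layer["h"], p[f"l{l}.W2"], ffn_out, R_ffn, eps)
        # activation: identity relevance pass; then first FFN linear
        R_ln1_ffn = _lrp_linear(ln1, p[f"l{l}.W1"], ln1 @ p[f"l{l}.W1"] + p[f"l{l}.b1"], R_h, eps)
        R_ln1_tot = R_ln1_res + R_ln1_ffn
        # ln1: pass through
        x_in, attn_out, res1 = layer["x_in"], layer["attn_out"], layer["res1"]
        s1 = _eps_div(R_ln1_tot, res1, eps)
        R_x_in_res, R_attn = x_in * s1, attn_out * s1
        ctx = layer["ctx"]
        R_ctx = _lrp_linear(ctx, p[f"l{l}.Wo"], attn_out, R_attn, eps)
        # attention as constant mixing: ctx_h = A @ v
        A, v = layer["A"], layer["v"]
        ctx_h = ctx.reshape(S, W, H, dh).transpose(0, 2, 1, 3)
        R_ctx_h = R_ctx.reshape(S, W, H, dh).transpose(0, 2, 1, 3)
        s_ctx = _eps_div(R_ctx_h, ctx_h, eps)
        R_v = v * np.matmul(A.transpose(0, 1, 3, 2), s_ctx)
        R_v_flat = R_v.transpose(0, 2, 1, 3).reshape(S, W, d)
        v_flat = v.transpose(0, 2, 1, 3).reshape(S, W, d)
        R_x_in_v = _lrp_linear(x_in, p[f"l{l}.Wv"], v_flat, R_v_flat, eps)
        R_x = R_x_in_res + R_x_in_v

    per_seg = R_x.sum(axis=-1) * mask
    scores = _stitch_masked(per_seg, mask, starts, len(ids))
    amap = TokenAttributionMap(doc_id, task, cls, "lrp", scores)
    if return_conservation:
        return amap, float(per_seg.sum()), float(logit[cls])
    return amap


METHODS = {
    "attention": attention_attribution,
    "lgxa": gradient_x_activation,
    "ig": integrated_gradients,
    "lrp": lrp,
}


def attribute(
    model: SegmentTransformer, ids, method: str, task: str | None = None,
    cls: int | None = None, doc_id=None, **kwargs
) -> TokenAttributionMap:
    """Dispatch to one of the four attribution methods."""
    if method == "attention":
        return attention_attribution(model, ids, doc_id=doc_id)
    if method not in METHODS:
        raise KeyError(f"unknown attribution method {method!r}")
    if task is None or cls is None:
        raise ValueError(f"method {method!r} requires task and class")
    return METHODS[method](model, ids, task, cls, doc_id=doc_id, **kwargs)
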