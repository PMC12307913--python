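"""End-to-end orchestration: generate → split → train → explain → aggregate → evaluate.

A single :class:`RunConfig` drives all stages; every stage derives its own
seed deterministically from the master seed, writes its outputs under the
run directory and records provenance in ``manifest.json``.  Stages whose
outputs already exist are skipped on re-runs, and deterministic stages
reproduce their outputs bit-identically for a fixed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bow as bow_mod
from . import phrases as ph
from .attribution import attribute
from .corpus_synth import default_config, generate_corpus
from .data_model import CARE_NEED, TASKS, Corpus, read_corpus, split_corpus, write_corpus, write_id_list
from .faithfulness import (
    aopc_global,
    expand_phrase_ranking,
    local_removal_curve,
    macro_f1,
    random_word_ranking,
)
from .phrases import merge_subtokens
from .transformer import SegmentTransformer, TransformerConfig, train_multitask

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    # generation
    n_docs: int = 1000
    mean_length: float = 120.0
    generator_overrides: dict = field(default_factory=dict)
    fractions: tuple = (0.70, 0.10, 0.20)
    # models
    models: tuple = ("bow",)
    bow_alpha: float = 1.0
    transformer: dict = field(default_factory=dict)  # TransformerConfig overrides
    # explanation
    methods: tuple = ("lrp", "ig")
    metrics: tuple = ("i_avg", "i_h")
    top_k: int = 20
    explain_sample: int = 100
    # evaluation
    run_eval: bool = False
    eval_docs: int = 100
    aopc_samples: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("fractions", "models", "methods", "metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"config": dataclasses.asdict(cfg), "config_hash": _config_hash(cfg),
                "stages": {}}

    def commit(stage, **info):
        manifest["stages"][stage] = {"seed": _stage_seed(cfg.seed, stage), **info}
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        corpus, registry = _stage_generate(cfg, out, commit)
        split = _stage_split(cfg, out, corpus, commit)
        results = {}
        if "bow" in cfg.models:
            results["bow"] = _stage_bow(cfg, out, corpus, split, commit)
        if "transformer" in cfg.models:
            results["transformer"] = _stage_transformer(cfg, out, corpus, split, commit)
        _stage_aggregate(cfg, out, corpus, split, results, commit)
        if cfg.run_eval and "transformer" in results:
            _stage_eval(cfg, out, corpus, split, results, commit)
    except Exception as exc:
        commit("failed", error=f"{type(exc).__name__}: {exc}")
        raise
    return out


def _stage_generate(cfg, out, commit):
    path, reg_path = out / "corpus.jsonl", out / "registry.json"
    gen_cfg = default_config(
        seed=_stage_seed(cfg.seed, "generate"),
        n_docs=cfg.n_docs,
        mean_length=cfg.mean_length,
        **cfg.generator_overrides,
    )
    corpus, registry = generate_corpus(gen_cfg)
    if not path.exists():
        write_corpus(corpus, path)
        with open(reg_path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "owners": {p: list(o) for p, o in registry.owners.items()},
                    "events": {
                        p: [[e.doc_id, e.position, list(e.realized_words)] for e in evs]
                        for p, evs in registry.events.items()
                    },
                },
                fh, ensure_ascii=False, indent=1,
            )
    commit("generate", n_docs=len(corpus))
    return corpus, registry


def _stage_split(cfg, out, corpus, commit):
    split = split_corpus(
        [d.doc_id for d in corpus.documents], cfg.fractions,
        seed=_stage_seed(cfg.seed, "split"),
    )
    sdir = out / "splits"
    sdir.mkdir(exist_ok=True)
    for name, ids in (("train", split.train_ids), ("val", split.val_ids),
                      ("test", split.test_ids)):
        write_id_list(ids, sdir / f"{name}.txt")
    commit("split", sizes=split.sizes)
    return split


def _stage_bow(cfg, out, corpus, split, commit):
    model, X_train, train_ids = bow_mod.fit_bow_on_corpus(
        corpus, split.train_ids, alpha=cfg.bow_alpha
    )
    bow_mod.save_model(model, out / "bow")
    test = corpus.subset(split.test_ids)
    X_test = model.feature_space.transform([d.text for d in test.documents])
    rows = []
    for task in TASKS:
        preds = model.predict(X_test, task)
        truth = test.label_array(task, coarse=True)
        rows.append({"task": task, "macro_f1": macro_f1(preds, truth, range(3))})
    pd.DataFrame(rows).to_csv(out / "bow" / "metrics.tsv", sep="\t", index=False)
    commit("train_bow", n_features=len(model.feature_space.vocabulary))
    return {"model": model, "X_train": X_train, "train_ids": train_ids}


def _stage_transformer(cfg, out, corpus, split, commit):
    overrides = dict(cfg.transformer)
    overrides.setdefault("seed", _stage_seed(cfg.seed, "train_txf"))
    tcfg = TransformerConfig(**overrides)
    model, history = train_multitask(corpus, split, tcfg)
    model.save(out / "txf")
    pd.DataFrame(history.epochs, columns=["epoch", "train_loss", "val_f1"]).to_csv(
        out / "txf" / "training_log.tsv", sep="\t", index=False
    )
    commit("train_txf", best_epoch=history.best_epoch, best_val_f1=history.best_val_f1)
    return {"model": model}


def transformer_phrase_records(
    model: SegmentTransformer, corpus: Corpus, doc_ids, method: str,
    tasks=TASKS, max_docs: int | None = None,
) -> pd.DataFrame:
    """Local explanations of predicted classes, merged into phrase records."""
    frames = []
    ids_iter = list(doc_ids)[: max_docs or len(doc_ids)]
    sub = corpus.subset(ids_iter)
    for doc in sub.documents:
        enc = model.encode_doc(doc.words)
        preds, _ = model.predict_doc(enc.ids)
        for task in tasks:
            if method == "attention":
                amap = attribute(model, enc.ids, "attention", doc_id=doc.doc_id)
            else:
                amap = attribute(
                    model, enc.ids, method, task=task, cls=preds[task],
                    doc_id=doc.doc_id,
                )
            word_scores = merge_subtokens(amap.scores, enc.word_ids)
            frames.append(
                ph.phrase_records(doc.doc_id, task, doc.words, word_scores)
            )
    if not frames:
        return pd.DataFrame(columns=list(ph.RECORD_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def _stage_aggregate(cfg, out, corpus, split, results, commit):
    tables_dir = out / "tables"
    tables_dir.mkdir(exist_ok=True)
    emitted = []
    scored = {}
    if "bow" in results:
        totals = bow_mod.bow_global_totals(
            results["bow"]["model"], results["bow"]["X_train"]
        )
        scored[("bow", "coef")] = ph.homogeneity_from_totals(totals)
    if "transformer" in results:
        for method in cfg.methods:
            records = transformer_phrase_records(
                results["transformer"]["model"], corpus, split.train_ids, method,
                max_docs=cfg.explain_sample,
            )
            scored[("transformer", method)] = ph.aggregate_homogeneity(records)
    for (model_name, method), scores in scored.items():
        scores.to_csv(
            out / f"scores_{model_name}_{method}.tsv", sep="\t", index=False
        )
        for metric in cfg.metrics:
            for task in TASKS:
                if scores.empty or task not in set(scores["task"]):
                    continue
                table = ph.top_phrases(
                    scores, task, k=cfg.top_k, metric=metric, corpus=corpus
                )
                name = f"{model_name}_{method}_{metric}_{task}.tsv"
                table.to_csv(tables_dir / name, sep="\t", index=False)
                emitted.append(name)
    commit("aggregate", n_tables=len(emitted))
    return scored


def _stage_eval(cfg, out, corpus, split, results, commit):
    model = results["transformer"]["model"]
    eval_ids = split.test_ids[: cfg.eval_docs]
    curves = []
    for method in list(cfg.methods) + ["random"]:
        if method == "random":
            ranker = "random"
        else:
            def ranker(doc, ids, _m=method):
                preds, _ = model.predict_doc(ids)
                amap = attribute(model, ids, _m, task=CARE_NEED, cls=preds[CARE_NEED])
                return amap.scores
        curve = local_removal_curve(
            model, corpus, eval_ids, ranker, seed=_stage_seed(cfg.seed, "eval")
        )
        curves.append((method, curve))
    rows = [
        {"method": m, "step": s, "value": v}
        for m, c in curves
        for s, v in zip(c.steps, c.values)
    ]
    edir = out / "eval"
    edir.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(edir / "local_removal.tsv", sep="\t", index=False)
    _plot_curves(curves, edir / "local_removal.png")
    commit("eval", n_curves=len(curves))


def _plot_curves(curves, path):
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for method, curve in curves:
        ax.plot(curve.steps, curve.values, marker="o", label=method)
    ax.set_xlabel("fraction of tokens removed")
    ax.set_ylabel("care-need macro F1")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
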