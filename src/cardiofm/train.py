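"""Pretraining loop, fine-tuning with layer-wise LR decay, frozen feature
extraction and evaluation metrics.

Defaults follow the reference training recipe: AdamW with betas (0.9, 0.95)
and weight decay 5e-2, linear warmup over the initial 5% of training
followed by cosine decay, validation-based early stopping at a fixed
evaluation cadence, uniform sampling across corpus sources per minibatch,
and a layer-wise learning-rate decay of 0.75 for fine-tuning (blocks nearer
the input receive geometrically smaller learning rates; the task head uses
the base rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, mean_absolute_error, r2_score, roc_auc_score

from . import heads as heads_mod
from . import nn
from .autograd import Tensor, no_grad
from .model import (CSFM, encode_uniform, full_visibility_plan,
                    pretrain_forward)
from .signals import SignalRecord, preprocess_signal, segment_signal
from .synth import Corpus
from .text import Vocabulary, encode_text


@dataclass
class TrainConfig:
    """Optimizer / schedule / loop hyperparameters."""

    base_lr: float = 5e-4
    batch_size: int = 16
    max_steps: int = 2000
    warmup_frac: float = 0.05
    eval_every: int = 250
    patience: int = 8                  # evaluations without improvement
    betas: tuple = (0.9, 0.95)
    weight_decay: float = 5e-2
    layerwise_decay: float = 0.75
    seed: int = 0
    val_cap: int = 32                  # max validation records per eval
    label_fraction: float = 1.0        # fine-tuning: fraction of train labels used
    head_warmup_frac: float = 0.0      # initial fraction of steps with frozen
                                       # encoder (linear-probe-then-fine-tune)

    def __post_init__(self):
        if not 0 <= self.warmup_frac < 1:
            raise ValueError("warmup_frac must lie in [0, 1)")
        if not 0 < self.layerwise_decay <= 1:
            raise ValueError("layerwise decay must lie in (0, 1]")


@dataclass
class TaskSpec:
    """A downstream supervised task defined on corpus ground truth."""

    kind: str                          # 'binary' | 'multiclass' | 'multilabel' | 'regression'
    n_classes: int
    target_fn: object                  # GroundTruth -> label / value

    def __post_init__(self):
        if self.kind not in ("binary", "multiclass", "multilabel", "regression"):
            raise ValueError(f"unknown task kind {self.kind!r}")


# ----------------------------------------------------------------------
_NO_DECAY_NAMES = ("table", "cls_token", "mask_token", "type_emb",
                   "bias", "gamma", "beta")


def _is_no_decay(name: str, p) -> bool:
    # biases, norm affines, the CLS/mask tokens and all embedding tables are
    # exempt from weight decay (standard AdamW practice; decaying the weakly
    # supervised CLS token in particular degrades the global representation)
    return p.data.ndim == 1 or any(tag in name for tag in _NO_DECAY_NAMES)


def split_decay_groups(module: nn.Module, lr_scale: float = 1.0,
                       name: str = "") -> list[dict]:
    """Split a module's parameters into decay / no-decay AdamW groups."""
    decay, no_decay = [], []
    for pname, p in module.named_parameters():
        (no_decay if _is_no_decay(pname, p) else decay).append(p)
    groups = []
    if decay:
        groups.append({"params": decay, "lr_scale": lr_scale,
                       "name": f"{name}:decay" if name else "decay"})
    if no_decay:
        groups.append({"params": no_decay, "lr_scale": lr_scale,
                       "weight_decay": 0.0,
                       "name": f"{name}:no_decay" if name else "no_decay"})
    return groups


def layerwise_lr_groups(model: CSFM, head: nn.Module | None, base_lr: float,
                        decay: float):
    """Parameter groups with geometrically decayed LRs.

    With D encoder blocks, block k (k = 1 nearest the input) trains at
    base_lr * decay^(D - k); the input embedders sit one step below block 1;
    the final norm and the task head train at base_lr.  The ratio between
    adjacent blocks is exactly `decay`.
    """
    if decay <= 0:
        raise ValueError("decay must be positive")
    D = len(model.blocks)
    # scales built by successive multiplication so that adjacent blocks
    # satisfy lr_k == decay * lr_{k+1} exactly in floating point
    scales = [1.0]
    for _ in range(D):
        scales.append(scales[-1] * decay)
    scales = scales[::-1]          # scales[k] = decay^(D-k); scales[0] = decay^D
    named: list[tuple[str, float, list]] = []
    embed_named = (list(model.signal_embedder.named_parameters("signal"))
                   + list(model.text_embedder.named_parameters("text"))
                   + [("cls_token", model.cls_token)])
    named.append(("embedders", scales[0], embed_named))
    for k, block in enumerate(model.blocks, start=1):
        named.append((f"block_{k}", scales[k],
                      list(block.named_parameters(f"block{k}"))))
    head_named = list(model.norm.named_parameters("norm"))
    if head is not None:
        head_named += list(head.named_parameters("task_head"))
    named.append(("head", 1.0, head_named))
    groups = []
    for gname, scale, params in named:
        decay = [p for n, p in params if not _is_no_decay(n, p)]
        nodecay = [p for n, p in params if _is_no_decay(n, p)]
        if decay:
            groups.append({"params": decay, "lr_scale": scale, "name": gname})
        if nodecay:
            groups.append({"params": nodecay, "lr_scale": scale,
                           "weight_decay": 0.0, "name": f"nd_{gname}"})
    for g in groups:
        g["lr"] = base_lr * g["lr_scale"]
    return groups


# ----------------------------------------------------------------------
def prepare_items(corpus: Corpus, model: CSFM, vocab: Vocabulary | None,
                  with_text: bool = True):
    """Preprocess + segment every record once; returns (PatchSet, ids|None)."""
    items = []
    for rec, tr in zip(corpus.records, corpus.truths):
        pre = preprocess_signal(rec)
        patches = segment_signal(pre, model.cfg.patch_seconds)
        text = None
        if with_text and vocab is not None and tr.report is not None:
            text = encode_text(tr.report, vocab, model.cfg.n_l)
        items.append((patches, text))
    return items


@dataclass
class PretrainResult:
    model: CSFM
    history: dict
    best_val: float
    best_state: dict


def run_pretraining(corpora: list[Corpus], model: CSFM,
                    vocab: Vocabulary | None, cfg: TrainConfig) -> PretrainResult:
    """Masked multimodal pretraining over one or more corpus sources.

    Each minibatch is drawn from one source chosen uniformly at random;
    validation loss (total masked reconstruction loss on held-out records,
    under masks resampled identically at every evaluation) drives early
    stopping, and the best checkpoint seen is restored at the end.
    """
    if not corpora or any(len(c) == 0 for c in corpora):
        raise ValueError("every pretraining source must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    train_items, val_items = [], []
    for corpus in corpora:
        tr_idx, va_idx, _ = corpus.split()
        items = prepare_items(corpus, model, vocab)
        train_items.append([items[i] for i in tr_idx])
        val_items.extend(items[i] for i in va_idx[:cfg.val_cap])
    val_items = val_items[:cfg.val_cap]

    opt = nn.AdamW(split_decay_groups(model), lr=cfg.base_lr,
                   betas=cfg.betas, weight_decay=cfg.weight_decay)
    history = {"train_loss": [], "val_steps": [], "val_total": [],
               "val_L_S": [], "val_L_L": [], "source_choices": []}
    best_val = np.inf
    best_state = model.state_dict()
    stale = 0

    def evaluate(step):
        ev_rng = np.random.default_rng(cfg.seed + 10_007)
        totals, ls_vals, ll_vals = [], [], []
        with no_grad():
            for i in range(0, len(val_items), cfg.batch_size):
                losses = pretrain_forward(model, val_items[i:i + cfg.batch_size],
                                          ev_rng)
                totals.append(losses["total"].item())
                if "L_S" in losses:
                    ls_vals.append(losses["L_S"].item())
                if "L_L" in losses:
                    ll_vals.append(losses["L_L"].item())
        history["val_steps"].append(step)
        history["val_total"].append(float(np.mean(totals)))
        history["val_L_S"].append(float(np.mean(ls_vals)) if ls_vals else np.nan)
        history["val_L_L"].append(float(np.mean(ll_vals)) if ll_vals else np.nan)
        return history["val_total"][-1]

    evaluate(0)
    best_val = history["val_total"][0]
    for step in range(cfg.max_steps):
        src = int(rng.integers(len(train_items)))
        history["source_choices"].append(src)
        pool = train_items[src]
        take = min(cfg.batch_size, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        batch = [pool[i] for i in idx]
        losses = pretrain_forward(model, batch, rng)
        model.zero_grad()
        losses["total"].backward()
        lr = nn.warmup_cosine_lr(step, cfg.max_steps, cfg.base_lr, cfg.warmup_frac)
        opt.step(lr)
        history["train_loss"].append(losses["total"].item())
        if (step + 1) % cfg.eval_every == 0:
            val = evaluate(step + 1)
            if val < best_val - 1e-12:
                best_val = val
                best_state = model.state_dict()
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if history["val_total"] and history["val_total"][0] <= best_val:
        # never return a checkpoint worse than the best seen (incl. init)
        best_val = history["val_total"][0]
    else:
        model.load_state_dict(best_state)
    return PretrainResult(model, history, float(best_val), best_state)


# ----------------------------------------------------------------------
def _encode_cls_batch(model: CSFM, patch_sets):
    """(B, d) CLS outputs; fused path for uniform layouts, ragged fallback."""
    try:
        x, _ = encode_uniform(model, patch_sets)
        return x[:, 0, :], None
    except ValueError:
        seqs = [model.assemble_input(p) for p in patch_sets]
        plans = [full_visibility_plan(s) for s in seqs]
        x, lengths, _ = model.encode_batch(seqs, plans)
        return x[:, 0, :], seqs


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(labels), k))
    out[np.arange(len(labels)), labels] = 1.0
    return out


@dataclass
class FinetuneResult:
    model: CSFM
    head: nn.Module
    metrics: dict
    history: dict = field(default_factory=dict)


def run_finetune(model: CSFM, corpus: Corpus, task: TaskSpec,
                 cfg: TrainConfig, finetune_encoder: bool = True) -> FinetuneResult:
    """Supervised adaptation of a (pretrained or fresh) encoder.

    Signal-only sequences, no masking; classification uses the asymmetric
    loss on one-hot targets, regression plain MSE.  Layer-wise LR decay is
    applied to the encoder; the head trains at the base rate.  Held-out
    metrics are computed on the corpus' subject-wise test split.
    """
    rng = np.random.default_rng(cfg.seed)
    tr_idx, va_idx, te_idx = corpus.split()
    if cfg.label_fraction < 1.0:
        n_keep = max(2, int(round(cfg.label_fraction * len(tr_idx))))
        if task.kind == "regression":
            keep = rng.choice(len(tr_idx), size=n_keep, replace=False)
            tr_idx = np.sort(tr_idx[keep])
        else:
            # stratified: preserve the class balance of the full train split
            labels_tr = np.array([task.target_fn(corpus.truths[i])
                                  for i in tr_idx]).astype(int)
            picked = []
            for cls in np.unique(labels_tr):
                pool = tr_idx[labels_tr == cls]
                n_cls = max(1, int(round(cfg.label_fraction * len(pool))))
                picked.append(rng.choice(pool, size=min(n_cls, len(pool)),
                                         replace=False))
            tr_idx = np.sort(np.concatenate(picked))
    patch_sets = [segment_signal(preprocess_signal(r), model.cfg.patch_seconds)
                  for r in corpus.records]
    targets = np.array([task.target_fn(tr) for tr in corpus.truths], dtype=float)

    head_rng = np.random.default_rng(cfg.seed + 1)
    if task.kind == "regression":
        head = heads_mod.RegressionHead(model.cfg.d, head_rng)
    else:
        head = heads_mod.ClassificationHead(
            model.cfg.d, task.n_classes, head_rng,
            multilabel=(task.kind == "multilabel"))
    if finetune_encoder:
        groups = layerwise_lr_groups(model, head, cfg.base_lr, cfg.layerwise_decay)
    else:
        groups = split_decay_groups(head)
    opt = nn.AdamW(groups, lr=cfg.base_lr, betas=cfg.betas,
                   weight_decay=cfg.weight_decay)
    # linear-probe phase: the head is trained on frozen features first so
    # random-head gradients do not distort a pretrained encoder
    warmup_steps = int(round(cfg.head_warmup_frac * cfg.max_steps)) \
        if finetune_encoder else 0
    opt_head = nn.AdamW(split_decay_groups(head), lr=cfg.base_lr,
                        betas=cfg.betas, weight_decay=cfg.weight_decay) \
        if warmup_steps else None

    def batch_loss(idx_batch, frozen_encoder: bool = False):
        if frozen_encoder:
            with no_grad():
                z_cls, _ = _encode_cls_batch(model,
                                             [patch_sets[i] for i in idx_batch])
        else:
            z_cls, _ = _encode_cls_batch(model, [patch_sets[i] for i in idx_batch])
        logits = head(z_cls)
        if task.kind == "regression":
            diff = logits.reshape(-1) - Tensor(targets[idx_batch])
            return (diff * diff).mean()
        onehot = _one_hot(targets[idx_batch].astype(int), task.n_classes)
        return heads_mod.asymmetric_loss(logits, onehot)

    def eval_score(idx_set):
        """Validation score, higher is better.

        Classification checkpoints are selected on validation macro-F1 (the
        reported metric) rather than the surrogate loss — at small label
        budgets the two decouple and loss-based selection can return a
        collapsed classifier.  Regression falls back to negative MSE.
        """
        if task.kind == "regression":
            with no_grad():
                vals = [batch_loss(idx_set[i:i + cfg.batch_size]).item()
                        for i in range(0, len(idx_set), cfg.batch_size)]
            return -float(np.mean(vals))
        scores = predict_scores(model, head,
                                [patch_sets[i] for i in idx_set], task)
        labels = targets[idx_set].astype(int)
        pred = scores.argmax(axis=1) if scores.ndim == 2 \
            else (scores >= 0.5).astype(int)
        return float(f1_score(labels, pred, average="macro"))

    history = {"train_loss": [], "val_steps": [], "val_score": []}
    best = (-np.inf, model.state_dict(), head.state_dict())
    stale = 0
    for step in range(cfg.max_steps):
        idx_batch = rng.choice(tr_idx, size=min(cfg.batch_size, len(tr_idx)),
                               replace=False)
        probe_phase = step < warmup_steps
        loss = batch_loss(idx_batch, frozen_encoder=probe_phase)
        model.zero_grad()
        head.zero_grad()
        loss.backward()
        lr = nn.warmup_cosine_lr(step, cfg.max_steps, cfg.base_lr, cfg.warmup_frac)
        (opt_head if probe_phase else opt).step(lr)
        history["train_loss"].append(loss.item())
        if len(va_idx) and (step + 1) % cfg.eval_every == 0:
            val = eval_score(va_idx)
            history["val_steps"].append(step + 1)
            history["val_score"].append(val)
            if val > best[0] + 1e-12:
                best = (val, model.state_dict(), head.state_dict())
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if np.isfinite(best[0]):
        model.load_state_dict(best[1])
        head.load_state_dict(best[2])

    scores = predict_scores(model, head, [patch_sets[i] for i in te_idx], task)
    metrics = compute_metrics(scores, targets[te_idx], task.kind)
    return FinetuneResult(model, head, metrics, history)


def predict_scores(model: CSFM, head, patch_sets, task: TaskSpec,
                   batch_size: int = 32) -> np.ndarray:
    outs = []
    with no_grad():
        for i in range(0, len(patch_sets), batch_size):
            z_cls, _ = _encode_cls_batch(model, patch_sets[i:i + batch_size])
            if task.kind == "regression":
                outs.append(head(z_cls).numpy().reshape(-1))
            else:
                outs.append(heads_mod.classify(z_cls, head).numpy())
    return np.concatenate(outs, axis=0)


def run_finetune_seeds(model_factory, corpus: Corpus, task: TaskSpec,
                       cfg: TrainConfig, seeds=(0, 1, 2)) -> dict:
    """Fine-tune once per seed and report mean +/- sd of each metric.

    `model_factory(seed)` must return a fresh model (pretrained weights
    loaded or randomly initialized) for each run.
    """
    per_seed = []
    for s in seeds:
        run_cfg = TrainConfig(**{**cfg.__dict__, "seed": int(s)})
        result = run_finetune(model_factory(s), corpus, task, run_cfg)
        per_seed.append(result.metrics)
    keys = per_seed[0].keys()
    agg = {k: {"values": [m[k] for m in per_seed],
               "mean": float(np.mean([m[k] for m in per_seed])),
               "sd": float(np.std([m[k] for m in per_seed]))}
           for k in keys}
    return agg


# ----------------------------------------------------------------------
def extract_embeddings(model: CSFM, records: list[SignalRecord],
                       batch_size: int = 32) -> np.ndarray:
    """Frozen z_cls features, one d-vector per record; no parameter updates."""
    patch_sets = [segment_signal(preprocess_signal(r), model.cfg.patch_seconds)
                  for r in records]
    outs = []
    with no_grad():
        for i in range(0, len(patch_sets), batch_size):
            z_cls, _ = _encode_cls_batch(model, patch_sets[i:i + batch_size])
            outs.append(z_cls.numpy())
    return np.concatenate(outs, axis=0)


# ----------------------------------------------------------------------
@dataclass
class DenseResult:
    head: heads_mod.DenseHead
    metrics: dict
    history: dict


def run_dense_training(model: CSFM, corpus: Corpus, input_channels: list[str],
                       target_fn, out_channels: int, cfg: TrainConfig,
                       finetune_encoder: bool = False) -> DenseResult:
    """Train the dense sequence-to-sequence head on waveform targets.

    `target_fn(record, truth)` returns the (out_channels, T) target waveform
    (z-scored per channel for scale-free MSE).  The encoder runs without
    masking; by default it stays frozen and only the head trains.  Held-out
    performance is reported as pooled R^2 and MAE over all test samples.
    """
    rng = np.random.default_rng(cfg.seed)
    tr_idx, va_idx, te_idx = corpus.split()
    patch_sets, seq_targets = [], []
    for rec, tr in zip(corpus.records, corpus.truths):
        sub = rec.select_channels(input_channels)
        patch_sets.append(segment_signal(preprocess_signal(sub),
                                         model.cfg.patch_seconds))
        seq_targets.append(np.asarray(target_fn(rec, tr), dtype=np.float64))
    n_time = patch_sets[0].n_time
    t_out = n_time * model.cfg.patch_len
    seq_targets = [t[:, :t_out] for t in seq_targets]

    head = heads_mod.DenseHead(model.cfg.d, model.cfg.patch_len, out_channels,
                               np.random.default_rng(cfg.seed + 1))
    if finetune_encoder:
        groups = layerwise_lr_groups(model, head, cfg.base_lr, cfg.layerwise_decay)
    else:
        groups = split_decay_groups(head)
    opt = nn.AdamW(groups, lr=cfg.base_lr, betas=cfg.betas,
                   weight_decay=cfg.weight_decay)

    def forward(idx_batch) -> Tensor:
        pred = heads_mod.dense_regress(model, [patch_sets[i] for i in idx_batch],
                                       head)
        truth = np.stack([seq_targets[i] for i in idx_batch])
        diff = pred - Tensor(truth)
        return (diff * diff).mean()

    history = {"train_loss": [], "val_steps": [], "val_loss": []}
    best = (np.inf, head.state_dict(), model.state_dict())
    stale = 0
    for step in range(cfg.max_steps):
        idx_batch = rng.choice(tr_idx, size=min(cfg.batch_size, len(tr_idx)),
                               replace=False)
        loss = forward(idx_batch)
        model.zero_grad()
        head.zero_grad()
        loss.backward()
        lr = nn.warmup_cosine_lr(step, cfg.max_steps, cfg.base_lr, cfg.warmup_frac)
        opt.step(lr)
        history["train_loss"].append(loss.item())
        if len(va_idx) and (step + 1) % cfg.eval_every == 0:
            with no_grad():
                val = float(np.mean([
                    forward(va_idx[i:i + cfg.batch_size]).item()
                    for i in range(0, len(va_idx), cfg.batch_size)]))
            history["val_steps"].append(step + 1)
            history["val_loss"].append(val)
            if val < best[0] - 1e-12:
                best = (val, head.state_dict(), model.state_dict())
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if np.isfinite(best[0]):
        head.load_state_dict(best[1])
        model.load_state_dict(best[2])

    preds = predict_dense(model, head, [patch_sets[i] for i in te_idx])
    truth = np.stack([seq_targets[i] for i in te_idx])
    metrics = {
        "r2": float(r2_score(truth.reshape(-1), preds.reshape(-1))),
        "mae": float(mean_absolute_error(truth.reshape(-1), preds.reshape(-1))),
    }
    return DenseResult(head, metrics, history)


def predict_dense(model: CSFM, head: heads_mod.DenseHead, patch_sets,
                  batch_size: int = 16) -> np.ndarray:
    outs = []
    with no_grad():
        for i in range(0, len(patch_sets), batch_size):
            outs.append(heads_mod.dense_regress(
                model, patch_sets[i:i + batch_size], head).numpy())
    return np.concatenate(outs, axis=0)


# ----------------------------------------------------------------------
def compute_metrics(scores: np.ndarray, labels: np.ndarray, kind: str) -> dict:
    """Task-appropriate metric report.

    macro-F1 for multiclass/multilabel, AUC for binary classification
    (macro-F1 also reported), MAE and R^2 for regression.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if kind == "regression":
        return {"mae": float(mean_absolute_error(labels, scores)),
                "r2": float(r2_score(labels, scores))}
    labels = labels.astype(int)
    if kind == "binary":
        if len(np.unique(labels)) < 2:
            raise ValueError("AUC undefined: labels contain a single class")
        pos = scores[:, 1] if scores.ndim == 2 else scores
        pred = (pos >= 0.5).astype(int) if scores.ndim == 1 \
            else scores.argmax(axis=1)
        return {"auc": float(roc_auc_score(labels, pos)),
                "macro_f1": float(f1_score(labels, pred, average="macro"))}
    if kind == "multiclass":
        pred = scores.argmax(axis=1)
        return {"macro_f1": float(f1_score(labels, pred, average="macro"))}
    # multilabel: labels (n, K) binary, scores (n, K) probabilities
    pred = (scores >= 0.5).astype(int)
    return {"macro_f1": float(f1_score(labels, pred, average="macro"))}


__all__ = [
    "TrainConfig", "TaskSpec", "PretrainResult", "FinetuneResult",
    "layerwise_lr_groups", "run_pretraining", "run_finetune",
    "run_finetune_seeds", "predict_scores", "extract_embeddings",
    "compute_metrics", "prepare_items", "run_dense_training", "predict_dense",
    "DenseResult",
]
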