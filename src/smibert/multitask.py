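"""Multitask fine-tuning with task tokens and an attention visibility mask.

Every input row is the ``T`` task-token ids followed by the SMILES token ids
and padding. The encoder output at task position ``t`` feeds task ``t``'s
own two-layer prediction head. Attention visibility implements the
information-flow rules:

* a task row may attend to itself and to every real SMILES position — it
  reads the molecule but not the other tasks;
* a SMILES row may attend to real SMILES positions only — SMILES tokens
  never see task tokens, keeping the fine-tuning input distribution
  consistent with pretraining;
* padding rows attend only to themselves (their outputs are unused).

Positional encoding is added to SMILES positions only, so task slots are
exchangeable: permuting task tokens together with their heads leaves every
prediction unchanged.

The training objective is the unweighted sum over tasks of per-task losses
(softmax cross-entropy for classification, mean-squared error for
regression), each averaged over that task's observed labels in the batch;
a task with no observed label in a batch contributes exactly zero loss and
zero gradient. Regression labels are z-scored per task on the training
split; the scaler is stored with the model and inverted at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .chem_text import Vocabulary, tokenize, encode
from .datasets import MoleculeRecord, TaskTable
from .encoder import (ModelConfig, ParameterSet, encoder_forward,
                      save_checkpoint, load_checkpoint)
from .pretrain import EncoderModel

__all__ = [
    "MultitaskBatch",
    "TaskHead",
    "FinetunedModel",
    "EarlyStopping",
    "build_multitask_batch",
    "multitask_forward",
    "multitask_loss",
    "finetune_loop",
    "save_finetuned",
    "load_finetuned",
]


@dataclass
class MultitaskBatch:
    input_ids: np.ndarray        # (B, T + L) task ids then SMILES ids then pads
    visibility: np.ndarray       # (B, T+L, T+L) bool
    positional_mask: np.ndarray  # (T + L,) bool, False at task positions
    labels: np.ndarray           # (B, T)
    observed: np.ndarray         # (B, T) bool
    n_tasks: int
    lengths: np.ndarray          # (B,) real SMILES token counts


@dataclass
class TaskHead:
    """A per-task 2-layer prediction head over the task-token feature."""

    task_name: str
    kind: str                    # "classification" | "regression"
    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    @property
    def out_width(self) -> int:
        return 2 if self.kind == "classification" else 1

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]

    @classmethod
    def create(cls, task_name: str, kind: str, embed_size: int,
               rng: np.random.Generator, hidden_size: int | None = None,
               init_scale: float = 0.02) -> "TaskHead":
        if kind not in ("classification", "regression"):
            raise ValueError(f"unknown task kind {kind!r}")
        hidden = hidden_size or embed_size
        out = 2 if kind == "classification" else 1
        return cls(
            task_name, kind,
            w1=Tensor(rng.normal(0, init_scale, (embed_size, hidden)),
                      requires_grad=True),
            b1=Tensor(np.zeros(hidden), requires_grad=True),
            w2=Tensor(rng.normal(0, init_scale, (hidden, out)),
                      requires_grad=True),
            b2=Tensor(np.zeros(out), requires_grad=True),
        )

    def forward(self, feats: Tensor, dropout_rate: float = 0.0,
                train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        h = ad.gelu(ad.matmul(feats, self.w1) + self.b1)
        h = ad.dropout(h, dropout_rate, rng, train)
        out = ad.matmul(h, self.w2) + self.b2
        return out if self.kind == "classification" else out.reshape(out.shape[0])


@dataclass
class FinetunedModel:
    """Encoder + per-task heads + label scalers, ready for prediction."""

    config: ModelConfig
    params: ParameterSet
    vocab: Vocabulary
    heads: list[TaskHead]
    scalers: list[tuple[float, float] | None]  # (mean, std) per regression task

    @property
    def task_names(self) -> list[str]:
        return [h.task_name for h in self.heads]

    @property
    def task_kinds(self) -> list[str]:
        return [h.kind for h in self.heads]


def build_multitask_batch(records: list[MoleculeRecord], vocab: Vocabulary,
                          n_tasks: int,
                          task_token_order: list[int] | None = None
                          ) -> MultitaskBatch:
    """Assemble records into a task-token-prefixed padded batch.

    ``task_token_order`` puts task token ``[T{order[j]}]`` at prefix slot
    ``j`` (default identity); labels/observed columns follow the same
    order, so heads must be permuted consistently by the caller. Because
    task slots carry no positional encoding and cannot attend to each
    other, predictions are invariant to this ordering.
    """
    if n_tasks > vocab.n_task_tokens:
        raise ValueError(
            f"{n_tasks} tasks exceed the vocabulary's {vocab.n_task_tokens} "
            "task tokens"
        )
    if not records:
        raise ValueError("empty batch")
    seqs = [np.array(encode(tokenize(r.smiles), vocab), dtype=np.int64)
            for r in records]
    lengths = np.array([len(s) for s in seqs])
    B, T, L = len(records), n_tasks, int(lengths.max())
    S = T + L
    order = list(task_token_order) if task_token_order is not None else list(range(T))
    if sorted(order) != list(range(T)):
        raise ValueError("task_token_order must be a permutation of 0..T-1")
    task_ids = np.array([vocab.task_id(t) for t in order], dtype=np.int64)
    input_ids = np.full((B, S), vocab.pad_id, dtype=np.int64)
    input_ids[:, :T] = task_ids
    vis = np.zeros((B, S, S), dtype=bool)
    for b, seq in enumerate(seqs):
        Lb = len(seq)
        input_ids[b, T:T + Lb] = seq
        # task rows: self + real SMILES positions
        for t in range(T):
            vis[b, t, t] = True
            vis[b, t, T:T + Lb] = True
        # SMILES rows: real SMILES positions only
        vis[b, T:T + Lb, T:T + Lb] = True
        # pad rows: self only
        for p in range(T + Lb, S):
            vis[b, p, p] = True
    positional_mask = np.ones(S, dtype=bool)
    positional_mask[:T] = False
    labels = np.stack([r.labels[:T][order] for r in records])
    observed = np.stack([r.observed[:T][order] for r in records])
    return MultitaskBatch(input_ids, vis, positional_mask, labels, observed,
                          n_tasks=T, lengths=lengths)


def multitask_forward(batch: MultitaskBatch, config: ModelConfig,
                      params: ParameterSet, heads: list[TaskHead],
                      train: bool = False,
                      rng: np.random.Generator | None = None,
                      return_attention: bool = False):
    """Encode the batch and apply each task's head to its task-token feature.

    Returns a list of per-task prediction Tensors: shape (B, 2) logits for
    classification, (B,) values for regression. With
    ``return_attention=True`` also returns the per-layer attention maps.
    """
    if len(heads) != batch.n_tasks:
        raise ValueError(
            f"{len(heads)} heads for {batch.n_tasks} task positions"
        )
    feats, maps = encoder_forward(batch.input_ids, config, params,
                                  batch.visibility, batch.positional_mask,
                                  train=train, rng=rng)
    preds = []
    for t, head in enumerate(heads):
        task_feat = feats[(slice(None), t)]  # (B, F)
        preds.append(head.forward(task_feat, config.dropout_rate, train, rng))
    if return_attention:
        return preds, maps
    return preds


def multitask_loss(predictions: list, labels: np.ndarray,
                   observed: np.ndarray, task_kinds: list[str]) -> Tensor:
    """Unweighted sum over tasks of per-task mean loss on observed labels."""
    labels = np.asarray(labels, dtype=np.float64)
    observed = np.asarray(observed, dtype=bool)
    if labels.shape != observed.shape or labels.shape[1] != len(task_kinds):
        raise ValueError("predictions/labels/observed shapes disagree")
    if observed.sum() == 0:
        raise ValueError("batch has no observed label for any task")
    total = None
    for t, kind in enumerate(task_kinds):
        rows = np.nonzero(observed[:, t])[0]
        if len(rows) == 0:
            continue
        pred = predictions[t]
        pred = pred if isinstance(pred, Tensor) else Tensor(pred)
        y = labels[rows, t]
        if kind == "classification":
            logp = ad.log_softmax(pred[rows], axis=-1)
            picked = logp[(np.arange(len(rows)), y.astype(np.int64))]
            task_loss = -picked.mean()
        else:
            diff = pred[rows] - y
            task_loss = (diff * diff).mean()
        total = task_loss if total is None else total + task_loss
    return total


class EarlyStopping:
    """Stop when the monitored loss has not improved for ``patience`` epochs.

    The first recorded value initializes the best; with a flat loss from
    epoch 1 and patience 20, training stops after epoch 21.
    """

    def __init__(self, patience: int = 20, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best: float | None = None
        self.best_epoch: int | None = None
        self.since_best = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record an epoch's loss; returns True if training should stop."""
        if self.best is None or value < self.best - self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self.since_best = 0
            return False
        self.since_best += 1
        return self.since_best >= self.patience


def fit_scalers(table: TaskTable) -> list[tuple[float, float] | None]:
    """Per-task (mean, std) on the training split for regression tasks."""
    train = [r for r in table.records if r.split == "train"] or table.records
    scalers: list[tuple[float, float] | None] = []
    for t, kind in enumerate(table.task_kinds):
        if kind != "regression":
            scalers.append(None)
            continue
        vals = np.array([r.labels[t] for r in train if r.observed[t]])
        if len(vals) == 0:
            scalers.append((0.0, 1.0))
            continue
        std = float(vals.std())
        scalers.append((float(vals.mean()), std if std > 0 else 1.0))
    return scalers


def _apply_scalers(labels: np.ndarray, task_kinds, scalers) -> np.ndarray:
    out = labels.copy()
    for t, (kind, sc) in enumerate(zip(task_kinds, scalers)):
        if kind == "regression" and sc is not None:
            mu, sd = sc
            out[:, t] = (out[:, t] - mu) / sd
    return out


def _validation_loss(records, vocab, n_tasks, config, params, heads,
                     task_kinds, scalers, batch_size: int = 64) -> float:
    """Mean multitask loss over a record list (no dropout)."""
    total, weight = 0.0, 0
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        batch = build_multitask_batch(chunk, vocab, n_tasks)
        if batch.observed.sum() == 0:
            continue
        preds = multitask_forward(batch, config, params, heads)
        z = _apply_scalers(batch.labels, task_kinds, scalers)
        loss = multitask_loss(preds, z, batch.observed, task_kinds)
        total += loss.item() * len(chunk)
        weight += len(chunk)
    if weight == 0:
        raise ValueError("validation split has no observed labels")
    return total / weight


def finetune_loop(pretrained: EncoderModel, table: TaskTable,
                  lr: float = 5e-5, batch_size: int = 64,
                  max_epochs: int = 200, patience: int = 20,
                  dropout_rate: float = 0.1, seed: int = 0,
                  clip_norm: float = 1.0,
                  copy_params: bool = True,
                  progress: bool = False,
                  ) -> tuple[FinetunedModel, list[dict]]:
    """Fine-tune a pretrained encoder on a multitask table.

    The table must carry split assignments; training runs on the ``train``
    split while the ``valid`` split is monitored for early stopping
    (patience in epochs, maximum ``max_epochs``); the best-validation
    weights are restored at the end. Defaults mirror the reference recipe
    (Adam, lr 5e-5, batch 64, dropout 0.1, patience 20, 200 epochs max).

    Returns the fine-tuned model and a per-epoch log of
    ``{"epoch", "train_loss", "valid_loss"}``.
    """
    if table.n_tasks < 1:
        raise ValueError("table has no tasks")
    if table.n_tasks > pretrained.vocab.n_task_tokens:
        raise ValueError("more tasks than reserved task tokens")
    rng = np.random.default_rng(seed)
    config = ModelConfig(
        pretrained.config.n_layers, pretrained.config.n_heads,
        pretrained.config.embed_size, pretrained.config.ffn_size,
        dropout_rate, pretrained.config.max_sequence_length,
        pretrained.config.vocab_size,
    )
    params = pretrained.params.copy() if copy_params else pretrained.params
    params.validate(config)
    vocab = pretrained.vocab
    heads = [TaskHead.create(name, kind, config.embed_size, rng)
             for name, kind in zip(table.task_names, table.task_kinds)]
    scalers = fit_scalers(table)

    train_recs = [r for r in table.records if r.split == "train"]
    valid_recs = [r for r in table.records if r.split == "valid"]
    if not train_recs:
        raise ValueError("table has no train-split records")
    if not valid_recs:
        raise ValueError("table has no valid-split records")

    trainable = params.encoder_parameters() + [p for h in heads
                                               for p in h.parameters()]
    opt = Adam(trainable, lr=lr)
    stopper = EarlyStopping(patience=patience)
    best_state = None
    log: list[dict] = []
    iterator = range(1, max_epochs + 1)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="finetune")
    for epoch in iterator:
        order = rng.permutation(len(train_recs))
        total, count = 0.0, 0
        for start in range(0, len(order), batch_size):
            chunk = [train_recs[i] for i in order[start:start + batch_size]]
            batch = build_multitask_batch(chunk, vocab, table.n_tasks)
            if batch.observed.sum() == 0:
                continue
            preds = multitask_forward(batch, config, params, heads,
                                      train=True, rng=rng)
            z = _apply_scalers(batch.labels, table.task_kinds, scalers)
            loss = multitask_loss(preds, z, batch.observed, table.task_kinds)
            opt.zero_grad()
            loss.backward()
            ad.clip_gradients(opt.params, clip_norm)
            opt.step()
            total += loss.item() * len(chunk)
            count += len(chunk)
        val = _validation_loss(valid_recs, vocab, table.n_tasks, config,
                               params, heads, table.task_kinds, scalers,
                               batch_size)
        log.append({"epoch": epoch, "train_loss": total / max(count, 1),
                    "valid_loss": val})
        improved_before = stopper.best
        stop = stopper.update(val, epoch)
        if improved_before is None or val < improved_before:
            best_state = (
                {k: t.data.copy() for k, t in params.items()},
                [[p.data.copy() for p in h.parameters()] for h in heads],
            )
        if stop:
            break
    if best_state is not None:
        pstate, hstate = best_state
        for k, t in params.items():
            if k in pstate:
                t.data = pstate[k].copy()
        for h, saved in zip(heads, hstate):
            for p, s in zip(h.parameters(), saved):
                p.data = s.copy()
    return FinetunedModel(config, params, vocab, heads, scalers), log


def save_finetuned(path, model: FinetunedModel) -> None:
    """Single-archive checkpoint: encoder weights, head weights, vocabulary,
    task metadata and label scalers."""
    params = ParameterSet(dict(model.params.items()))
    for i, h in enumerate(model.heads):
        params[f"head.{i}.w1"] = h.w1
        params[f"head.{i}.b1"] = h.b1
        params[f"head.{i}.w2"] = h.w2
        params[f"head.{i}.b2"] = h.b2
    save_checkpoint(path, model.config, params, extra={
        "stage": "finetuned",
        "vocab": list(model.vocab.id_to_token),
        "task_names": model.task_names,
        "task_kinds": model.task_kinds,
        "scalers": [list(s) if s is not None else None for s in model.scalers],
    })


def load_finetuned(path) -> FinetunedModel:
    config, params, extra = load_checkpoint(path)
    if extra.get("stage") != "finetuned":
        raise ValueError("checkpoint is not a fine-tuned model")
    toks = extra["vocab"]
    import re as _re
    vocab = Vocabulary(
        token_to_id={t: i for i, t in enumerate(toks)},
        id_to_token=tuple(toks),
        n_task_tokens=sum(1 for t in toks if _re.fullmatch(r"\[T\d+\]", t)),
    )
    heads = []
    for i, (name, kind) in enumerate(zip(extra["task_names"],
                                         extra["task_kinds"])):
        heads.append(TaskHead(
            name, kind,
            w1=params[f"head.{i}.w1"], b1=params[f"head.{i}.b1"],
            w2=params[f"head.{i}.w2"], b2=params[f"head.{i}.b2"],
        ))
    scalers = [tuple(s) if s is not None else None for s in extra["scalers"]]
    return FinetunedModel(config, params, vocab, heads, scalers)
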