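"""Prediction with test-time enumeration fusion, evaluation metrics, and
attention-based interpretability.

A molecule is predicted by enumerating several SMILES renderings of it,
predicting each, and fusing the per-rendering predictions — by arithmetic
mean by default (median available) — which corrects rendering-specific bias.
Classification outputs are class-1 probabilities; regression outputs are
returned on the original label scale (the training z-score is inverted).

Interpretability reads the attention row of a task token over the SMILES
positions: because the task representation is an attention-weighted sum of
SMILES token features, that row measures each token's contribution to the
task's molecular representation. Task similarity is summarized by averaging,
over a sample of molecules, the Pearson correlation between tasks'
attention-weight vectors, followed by average-linkage hierarchical
clustering on 1 - correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from sklearn.metrics import (accuracy_score, mean_squared_error, r2_score,
                             roc_auc_score)

from . import autodiff as ad
from .augment import enumerate_smiles
from .chem_text import TokenSequence, tokenize, encode
from .datasets import MoleculeRecord
from .multitask import FinetunedModel, build_multitask_batch, multitask_forward

__all__ = [
    "PredictionResult",
    "AttentionMap",
    "predict_with_fusion",
    "predict_records",
    "compute_metrics",
    "extract_task_attention",
    "task_correlation",
    "export_token_embeddings",
]


@dataclass
class PredictionResult:
    canonical_smiles: str
    per_task: np.ndarray      # (T,) fused values
    per_variant: np.ndarray   # (n_variants, T) raw per-rendering predictions
    variants: tuple[str, ...]
    task_names: list[str]


@dataclass
class AttentionMap:
    tokens: TokenSequence
    weights: np.ndarray       # one weight per SMILES token
    task_name: str
    layer: int                # encoder layer the row was read from
    self_weight: float        # attention mass the task kept on itself


def _raw_predictions(model: FinetunedModel, smiles_list: list[str]
                     ) -> np.ndarray:
    """(n, T) predictions: class-1 probability / un-z-scored regression."""
    records = [MoleculeRecord(s, np.zeros(len(model.heads)),
                              np.zeros(len(model.heads), dtype=bool))
               for s in smiles_list]
    batch = build_multitask_batch(records, model.vocab, len(model.heads))
    preds = multitask_forward(batch, model.config, model.params, model.heads)
    out = np.zeros((len(smiles_list), len(model.heads)))
    for t, head in enumerate(model.heads):
        if head.kind == "classification":
            probs = ad.softmax(preds[t], axis=-1).data
            out[:, t] = probs[:, 1]
        else:
            vals = preds[t].data
            sc = model.scalers[t]
            if sc is not None:
                mu, sd = sc
                vals = vals * sd + mu
            out[:, t] = vals
    return out


def predict_with_fusion(model: FinetunedModel, smiles: str,
                        n_variants: int = 20, seed: int = 0,
                        fusion: str = "mean") -> PredictionResult:
    """Predict one molecule through enumeration fusion.

    Enumerates up to ``n_variants`` renderings (canonical first; small
    molecules may yield fewer), predicts each, and fuses per task. The
    fused classification value is a probability in [0, 1] and always lies
    within [min, max] of the per-rendering probabilities.
    """
    if fusion not in ("mean", "median"):
        raise ValueError("fusion must be 'mean' or 'median'")
    enum = enumerate_smiles(smiles, n=n_variants, seed=seed)
    per_variant = _raw_predictions(model, list(enum.variants))
    fuse = np.mean if fusion == "mean" else np.median
    fused = fuse(per_variant, axis=0)
    return PredictionResult(
        canonical_smiles=enum.canonical,
        per_task=fused,
        per_variant=per_variant,
        variants=enum.variants,
        task_names=model.task_names,
    )


def predict_records(model: FinetunedModel, records: list[MoleculeRecord],
                    n_variants: int = 20, seed: int = 0,
                    fusion: str = "mean") -> np.ndarray:
    """Fused predictions for many records; returns an (n, T) matrix."""
    rng = np.random.default_rng(seed)
    out = np.zeros((len(records), len(model.heads)))
    for i, rec in enumerate(records):
        res = predict_with_fusion(model, rec.smiles, n_variants,
                                  seed=int(rng.integers(2**31)), fusion=fusion)
        out[i] = res.per_task
    return out


def compute_metrics(predictions: np.ndarray, labels: np.ndarray,
                    observed: np.ndarray, task_kinds: list[str],
                    task_names: list[str] | None = None,
                    threshold: float = 0.5) -> dict[str, dict]:
    """Per-task metrics over observed entries only.

    Classification: ROC-AUC and accuracy (probabilities thresholded at
    ``threshold``); regression: R^2 and RMSE. A task whose preconditions
    fail (no observed labels; a single class present for ROC-AUC) has that
    metric reported as None rather than a fabricated number.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    observed = np.asarray(observed, dtype=bool)
    names = task_names or [f"task{t}" for t in range(len(task_kinds))]
    report: dict[str, dict] = {}
    for t, (kind, name) in enumerate(zip(task_kinds, names)):
        rows = observed[:, t]
        entry: dict = {"kind": kind, "n_observed": int(rows.sum())}
        if rows.sum() == 0:
            entry.update({"roc_auc": None, "accuracy": None,
                          "r2": None, "rmse": None})
            report[name] = entry
            continue
        y, p = labels[rows, t], predictions[rows, t]
        if kind == "classification":
            entry["accuracy"] = float(accuracy_score(y, p >= threshold))
            entry["roc_auc"] = (float(roc_auc_score(y, p))
                                if len(np.unique(y)) == 2 else None)
        else:
            entry["r2"] = float(r2_score(y, p)) if len(y) >= 2 else None
            entry["rmse"] = float(np.sqrt(mean_squared_error(y, p)))
        report[name] = entry
    return report


def _task_attention_rows(model: FinetunedModel, smiles: str,
                         layer_policy: int | str = "last") -> tuple[np.ndarray, TokenSequence, int]:
    """Head-averaged attention rows of every task over one molecule.

    Returns (rows, tokens, layer) where rows is (T, L+1): column 0 is the
    task's self-weight, columns 1..L the weights over SMILES tokens.
    """
    seq = tokenize(smiles)
    T = len(model.heads)
    rec = MoleculeRecord(smiles, np.zeros(T), np.zeros(T, dtype=bool))
    batch = build_multitask_batch([rec], model.vocab, T)
    _, maps = multitask_forward(batch, model.config, model.params, model.heads,
                                return_attention=True)
    layer = len(maps) - 1 if layer_policy == "last" else int(layer_policy)
    attn = maps[layer][0]              # (H, S, S)
    mean_heads = attn.mean(axis=0)     # (S, S)
    L = len(seq)
    rows = np.zeros((T, L + 1))
    for t in range(T):
        rows[t, 0] = mean_heads[t, t]
        rows[t, 1:] = mean_heads[t, T:T + L]
    return rows, seq, layer


def extract_task_attention(model: FinetunedModel, smiles: str,
                           task_index: int,
                           layer_policy: int | str = "last") -> AttentionMap:
    """Per-token attention weights of one task over one molecule.

    Weights are the chosen layer's task-row attention mass, averaged over
    heads; together with the task's self-weight they sum to 1.
    """
    if not 0 <= task_index < len(model.heads):
        raise IndexError(f"task index {task_index} out of range")
    rows, seq, layer = _task_attention_rows(model, smiles, layer_policy)
    return AttentionMap(
        tokens=seq,
        weights=rows[task_index, 1:].copy(),
        task_name=model.heads[task_index].task_name,
        layer=layer,
        self_weight=float(rows[task_index, 0]),
    )


def task_correlation(model: FinetunedModel, molecule_sample: list[str],
                     layer_policy: int | str = "last"
                     ) -> tuple[np.ndarray, list[int]]:
    """Average Pearson correlation between tasks' attention-weight vectors.

    For each molecule, every task's weight vector over SMILES tokens is
    correlated with every other task's; correlations are averaged over the
    sample (pairs with a constant vector are skipped, and flagged as NaN if
    no molecule yields a defined value). Returns the (T, T) matrix and the
    dendrogram leaf order from average-linkage clustering on
    1 - correlation.
    """
    T = len(model.heads)
    if T < 2:
        raise ValueError("need at least 2 tasks")
    if not molecule_sample:
        raise ValueError("empty molecule sample")
    sums = np.zeros((T, T))
    counts = np.zeros((T, T))
    for smiles in molecule_sample:
        rows, _, _ = _task_attention_rows(model, smiles, layer_policy)
        vecs = rows[:, 1:]
        stds = vecs.std(axis=1)
        ok = stds > 0
        if ok.sum() < 2 or vecs.shape[1] < 2:
            continue
        c = np.corrcoef(vecs[ok])
        idx = np.nonzero(ok)[0]
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                sums[ia, ib] += c[a, b]
                counts[ia, ib] += 1
    with np.errstate(invalid="ignore"):
        corr = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(corr, 1.0)
    finite = np.nan_to_num(corr, nan=0.0)
    dist = squareform(np.clip(1.0 - finite, 0.0, None), checks=False)
    order = list(leaves_list(average(dist)))
    return corr, order


def export_token_embeddings(model, smiles_list: list[str]) -> pd.DataFrame:
    """One encoder-output feature row per token of each molecule.

    Accepts a pretrained :class:`~smibert.pretrain.EncoderModel` or a
    :class:`FinetunedModel`; no masking and no task tokens are applied, so
    the rows are the contextual token representations suitable for external
    projection (t-SNE, UMAP...). Molecules that fail to tokenize are
    skipped and reported in the ``skipped`` attribute of the frame.
    """
    from .encoder import encoder_forward
    from .pretrain import pretrain_visibility

    rows = []
    skipped: list[tuple[int, str]] = []
    for mol_id, smiles in enumerate(smiles_list):
        try:
            seq = tokenize(smiles)
            ids = np.array([encode(seq, model.vocab)], dtype=np.int64)
        except (ValueError, KeyError) as exc:
            skipped.append((mol_id, str(exc)))
            continue
        L = ids.shape[1]
        vis = pretrain_visibility(np.array([L]), L)
        feats, _ = encoder_forward(ids, model.config, model.params, vis)
        for pos, tok in enumerate(seq.tokens):
            rows.append((mol_id, tok, pos, feats.data[0, pos].copy()))
    frame = pd.DataFrame(
        {
            "molecule_id": [r[0] for r in rows],
            "token": [r[1] for r in rows],
            "position": [r[2] for r in rows],
        }
    )
    emb = np.stack([r[3] for r in rows]) if rows else np.zeros((0, model.config.embed_size))
    for j in range(emb.shape[1]):
        frame[f"f{j}"] = emb[:, j]
    frame.attrs["skipped"] = skipped
    return frame
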