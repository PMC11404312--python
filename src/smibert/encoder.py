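"""Transformer encoder for SMILES token sequences.

Architecture: token embedding through a dictionary D in R^{V x F}, plus a
fixed sinusoidal positional encoding at selected positions, followed by
``n_layers`` identical blocks of multi-head scaled dot-product self-attention
and a position-wise two-layer feed-forward network with GELU activation.
Both sublayers use residual connections with post-norm ordering (layer
normalization applied after the residual add). A boolean *visibility* matrix
restricts which positions may attend to which: forbidden pairs receive
exactly zero attention weight. Padding positions are excluded from attention
through this matrix, making real-token outputs invariant to the amount of
trailing padding.

Three size presets are provided (layers, heads, embedding width F, FFN
width): small (4, 4, 128, 512), medium (8, 8, 256, 1024) and
large (12, 12, 576, 2304).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ModelConfig",
    "ParameterSet",
    "positional_encoding",
    "scaled_attention",
    "encoder_forward",
    "init_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

PRESETS: dict[str, tuple[int, int, int, int]] = {
    "small": (4, 4, 128, 512),
    "medium": (8, 8, 256, 1024),
    "large": (12, 12, 576, 2304),
}

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Size and regularization settings for the encoder."""

    n_layers: int
    n_heads: int
    embed_size: int
    ffn_size: int
    dropout_rate: float = 0.1
    max_sequence_length: int = 200
    vocab_size: int = 0

    def __post_init__(self):
        if self.embed_size % self.n_heads != 0:
            raise ValueError(
                f"embed_size {self.embed_size} not divisible by n_heads {self.n_heads}"
            )

    @property
    def d_k(self) -> int:
        """Per-head key/query width, the attention scaling factor's square."""
        return self.embed_size // self.n_heads

    @classmethod
    def preset(cls, name: str, vocab_size: int, dropout_rate: float = 0.1,
               max_sequence_length: int = 200) -> "ModelConfig":
        try:
            layers, heads, embed, ffn = PRESETS[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(layers, heads, embed, ffn, dropout_rate,
                   max_sequence_length, vocab_size)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


class ParameterSet:
    """All learnable weights, as a flat name -> Tensor mapping.

    Keys: ``embed`` (the V x F dictionary), per layer ``layers.{i}.{name}``
    for attention projections (wq/wk/wv/wo with biases), FFN weights
    (w1/b1/w2/b2) and the two layer norms (ln1_g/ln1_b/ln2_g/ln2_b), plus
    whatever head weights training attaches (``mlm.*`` for the pretraining
    head, ``head.{task}.*`` for prediction heads).
    """

    def __init__(self, tensors: dict[str, Tensor]):
        self.tensors = tensors

    def __getitem__(self, key: str) -> Tensor:
        return self.tensors[key]

    def __setitem__(self, key: str, value: Tensor) -> None:
        self.tensors[key] = value

    def __contains__(self, key: str) -> bool:
        return key in self.tensors

    def items(self):
        return self.tensors.items()

    def parameters(self, prefix: str | None = None) -> list[Tensor]:
        if prefix is None:
            return list(self.tensors.values())
        return [t for k, t in self.tensors.items() if k.startswith(prefix)]

    def encoder_parameters(self) -> list[Tensor]:
        """Embedding + transformer block weights (no heads)."""
        return [t for k, t in self.tensors.items()
                if k == "embed" or k.startswith("layers.")]

    def copy(self) -> "ParameterSet":
        """Deep copy (fresh Tensors; gradients not carried over)."""
        return ParameterSet({
            k: Tensor(t.data.copy(), requires_grad=t.requires_grad)
            for k, t in self.tensors.items()
        })

    def validate(self, config: ModelConfig) -> None:
        """Check array shapes against the config; raise on mismatch."""
        F, FF, V = config.embed_size, config.ffn_size, config.vocab_size
        expect = {"embed": (V, F)}
        for i in range(config.n_layers):
            p = f"layers.{i}."
            expect.update({
                p + "wq": (F, F), p + "wk": (F, F), p + "wv": (F, F),
                p + "wo": (F, F), p + "bq": (F,), p + "bk": (F,),
                p + "bv": (F,), p + "bo": (F,),
                p + "w1": (F, FF), p + "b1": (FF,),
                p + "w2": (FF, F), p + "b2": (F,),
                p + "ln1_g": (F,), p + "ln1_b": (F,),
                p + "ln2_g": (F,), p + "ln2_b": (F,),
            })
        for name, shape in expect.items():
            if name not in self.tensors:
                raise ValueError(f"missing parameter {name!r}")
            got = self.tensors[name].shape
            if tuple(got) != shape:
                raise ValueError(f"parameter {name!r} has shape {got}, expected {shape}")
            if not np.all(np.isfinite(self.tensors[name].data)):
                raise ValueError(f"parameter {name!r} contains non-finite values")


def init_parameters(config: ModelConfig, rng: np.random.Generator,
                    init_scale: float = 0.02) -> ParameterSet:
    """Initialize encoder weights: N(0, init_scale) matrices, zero biases,
    unit layer-norm scales."""
    F, FF, V = config.embed_size, config.ffn_size, config.vocab_size
    if V <= 0:
        raise ValueError("config.vocab_size must be set before initialization")

    def w(*shape):
        return Tensor(rng.normal(0.0, init_scale, shape), requires_grad=True)

    def zeros(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    def ones(*shape):
        return Tensor(np.ones(shape), requires_grad=True)

    tensors: dict[str, Tensor] = {"embed": w(V, F)}
    for i in range(config.n_layers):
        p = f"layers.{i}."
        tensors[p + "wq"] = w(F, F); tensors[p + "bq"] = zeros(F)
        tensors[p + "wk"] = w(F, F); tensors[p + "bk"] = zeros(F)
        tensors[p + "wv"] = w(F, F); tensors[p + "bv"] = zeros(F)
        tensors[p + "wo"] = w(F, F); tensors[p + "bo"] = zeros(F)
        tensors[p + "w1"] = w(F, FF); tensors[p + "b1"] = zeros(FF)
        tensors[p + "w2"] = w(FF, F); tensors[p + "b2"] = zeros(F)
        tensors[p + "ln1_g"] = ones(F); tensors[p + "ln1_b"] = zeros(F)
        tensors[p + "ln2_g"] = ones(F); tensors[p + "ln2_b"] = zeros(F)
    return ParameterSet(tensors)


def positional_encoding(length: int, embed_size: int,
                        max_sequence_length: int | None = None) -> np.ndarray:
    """Fixed sinusoidal positional table, shape (length, embed_size).

    Column 2i holds sin(pos / 10000^(2i/F)), column 2i+1 the matching cos.
    """
    if max_sequence_length is not None and length > max_sequence_length:
        raise ValueError(
            f"length {length} exceeds max_sequence_length {max_sequence_length}"
        )
    pos = np.arange(length)[:, None].astype(np.float64)
    i = np.arange(0, embed_size, 2).astype(np.float64)
    angles = pos / np.power(10000.0, i / embed_size)
    pe = np.zeros((length, embed_size))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles[:, : embed_size // 2])
    return pe


def _visibility_bias(visibility: np.ndarray) -> np.ndarray:
    """Boolean visibility -> additive bias (-inf at forbidden positions).

    Accepts (N, N) or (B, N, N); returns shape broadcastable to
    (B, H, N, N). Raises if any row permits no position.
    """
    vis = np.asarray(visibility, dtype=bool)
    if not vis.any(axis=-1).all():
        raise ValueError("visibility has a row permitting no position")
    bias = np.where(vis, 0.0, -np.inf)
    if bias.ndim == 2:
        return bias[None, None, :, :]
    if bias.ndim == 3:
        return bias[:, None, :, :]
    raise ValueError("visibility must be 2- or 3-dimensional")


def scaled_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                     d_k: float | None = None,
                     visibility: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention softmax(Q K^T / sqrt(d_k)) V.

    Plain-array entry point (no gradient tracking) operating on one matrix
    or any batch of leading axes. Forbidden positions of ``visibility``
    contribute exactly zero weight. Returns (output, weights).
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if d_k is None:
        d_k = Q.shape[-1]
    logits = np.matmul(Q, np.swapaxes(K, -1, -2)) / math.sqrt(d_k)
    if visibility is not None:
        vis = np.asarray(visibility, dtype=bool)
        if not vis.any(axis=-1).all():
            raise ValueError("visibility has a row permitting no position")
        logits = np.where(vis, logits, -np.inf)
    zmax = np.max(logits, axis=-1, keepdims=True)
    zmax = np.where(np.isfinite(zmax), zmax, 0.0)
    e = np.exp(logits - zmax)
    weights = e / e.sum(axis=-1, keepdims=True)
    return np.matmul(weights, V), weights


def _linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return ad.matmul(x, w) + b


def encoder_forward(ids: np.ndarray, config: ModelConfig, params: ParameterSet,
                    visibility: np.ndarray,
                    positional_mask: np.ndarray | None = None,
                    train: bool = False,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[Tensor, list[np.ndarray]]:
    """Run the encoder.

    Parameters
    ----------
    ids : (B, N) integer token ids.
    visibility : (N, N) or (B, N, N) boolean, True where position i may
        attend to position j.
    positional_mask : (N,) or (B, N) boolean; positional encoding is added
        only where True (task-token positions are excluded during
        fine-tuning). None means all positions.
    train : enables dropout (requires ``rng``).

    Returns
    -------
    features : Tensor of shape (B, N, F).
    attention_maps : list of per-layer weight arrays, each (B, H, N, N).
    """
    ids = np.asarray(ids)
    if ids.ndim != 2:
        raise ValueError("ids must be a (batch, length) matrix")
    B, N = ids.shape
    if ids.max(initial=0) >= config.vocab_size or ids.min(initial=0) < 0:
        raise ValueError("token id out of vocabulary range")
    if train and rng is None:
        raise ValueError("training mode requires an rng for dropout")
    F, H = config.embed_size, config.n_heads
    d_k = config.d_k
    drop = config.dropout_rate

    # embeddings are scaled by sqrt(F) so the fixed positional encoding
    # (entries in [-1, 1]) does not swamp the token signal
    x = ad.embedding(params["embed"], ids) * math.sqrt(F)  # (B, N, F)
    pe = positional_encoding(N, F, config.max_sequence_length)
    if positional_mask is None:
        x = x + pe
    else:
        pm = np.asarray(positional_mask, dtype=bool)
        if pm.ndim == 1:
            pm = pm[None, :]
        x = x + pe * pm[:, :, None]

    bias = _visibility_bias(visibility)
    maps: list[np.ndarray] = []
    for layer in range(config.n_layers):
        p = f"layers.{layer}."
        # multi-head self-attention
        q = _linear(x, params[p + "wq"], params[p + "bq"])
        k = _linear(x, params[p + "wk"], params[p + "bk"])
        v = _linear(x, params[p + "wv"], params[p + "bv"])
        # (B, N, F) -> (B, H, N, d_k)
        q = q.reshape(B, N, H, d_k).transpose((0, 2, 1, 3))
        k = k.reshape(B, N, H, d_k).transpose((0, 2, 1, 3))
        v = v.reshape(B, N, H, d_k).transpose((0, 2, 1, 3))
        logits = ad.matmul(q, k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(d_k))
        attn = ad.softmax(logits, axis=-1, bias=bias)
        maps.append(attn.data)
        if train:
            attn = ad.dropout(attn, drop, rng, train)
        ctx = ad.matmul(attn, v)  # (B, H, N, d_k)
        ctx = ctx.transpose((0, 2, 1, 3)).reshape(B, N, F)
        out = _linear(ctx, params[p + "wo"], params[p + "bo"])
        out = ad.dropout(out, drop, rng, train)
        x = ad.layer_norm(x + out, params[p + "ln1_g"], params[p + "ln1_b"])
        # position-wise FFN
        h = ad.gelu(_linear(x, params[p + "w1"], params[p + "b1"]))
        h = _linear(h, params[p + "w2"], params[p + "b2"])
        h = ad.dropout(h, drop, rng, train)
        x = ad.layer_norm(x + h, params[p + "ln2_g"], params[p + "ln2_b"])
    return x, maps


def save_checkpoint(path, config: ModelConfig, params: ParameterSet,
                    extra: dict | None = None) -> None:
    """Write config + all parameter arrays to a single .npz archive.

    ``extra`` may carry JSON-serializable metadata (vocabulary tokens, task
    names/kinds, label scalers...).
    """
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": json.loads(config.to_json()),
        "extra": extra or {},
    }
    arrays = {"param:" + k: t.data for k, t in params.items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[ModelConfig, ParameterSet, dict]:
    """Load a checkpoint; validates encoder shapes against its config."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
        if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"unsupported checkpoint format {meta.get('format_version')!r}"
            )
        tensors = {
            k[len("param:"):]: Tensor(npz[k], requires_grad=True)
            for k in npz.files if k.startswith("param:")
        }
    config = ModelConfig.from_json(json.dumps(meta["config"]))
    params = ParameterSet(tensors)
    params.validate(config)
    return config, params, meta.get("extra", {})
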