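import math

import numpy as np
import pytest

from smibert import (ModelConfig, encoder_forward, load_checkpoint,
                     positional_encoding, save_checkpoint, scaled_attention)
from smibert.encoder import PRESETS, init_parameters
from smibert.pretrain import pretrain_visibility

RNG = np.random.default_rng(7)


def brute_force_attention(Q, K, V, d_k, visibility=None):
    """Independent oracle: explicit per-row exp/normalize loops."""
    n, m = Q.shape[0], K.shape[0]
    out = np.zeros((n, V.shape[1]))
    W = np.zeros((n, m))
    for i in range(n):
        logits = np.array([Q[i] @ K[j] / math.sqrt(d_k) for j in range(m)])
        allowed = (np.ones(m, dtype=bool) if visibility is None
                   else np.asarray(visibility)[i])
        e = np.zeros(m)
        e[allowed] = np.exp(logits[allowed] - logits[allowed].max())
        W[i] = e / e.sum()
        out[i] = W[i] @ V
    return out, W


def test_positional_encoding_closed_form():
    pe = positional_encoding(5, 8)
    assert np.allclose(pe[0, 0::2], 0.0)   # sin(0)
    assert np.allclose(pe[0, 1::2], 1.0)   # cos(0)
    assert pe.min() >= -1.0 and pe.max() <= 1.0
    assert np.array_equal(pe, positional_encoding(5, 8))
    assert pe[1, 0] == pytest.approx(math.sin(1.0))
    with pytest.raises(ValueError):
        positional_encoding(10, 8, max_sequence_length=5)


def test_attention_single_token_returns_value():
    v = np.array([[3.0, -1.0]])
    out, w = scaled_attention(np.ones((1, 4)), np.ones((1, 4)), v)
    assert np.allclose(out, v)
    assert w[0, 0] == pytest.approx(1.0)


def test_attention_identical_keys_average_values():
    K = np.tile(RNG.standard_normal(3), (2, 1))
    V = np.array([[1.0, 5.0], [3.0, 7.0]])
    out, w = scaled_attention(RNG.standard_normal((1, 3)), K, V)
    assert np.allclose(out, [[2.0, 6.0]])
    assert np.allclose(w, 0.5)


def test_attention_matches_brute_force_oracle():
    for _ in range(100):
        n = int(RNG.integers(1, 7))
        d = int(RNG.integers(1, 9))
        Q, K = RNG.standard_normal((2, n, d))
        V = RNG.standard_normal((n, d))
        vis = RNG.random((n, n)) < 0.7
        vis[np.arange(n), np.arange(n)] = True  # every row permits >= 1
        out, w = scaled_attention(Q, K, V, visibility=vis)
        ref_out, ref_w = brute_force_attention(Q, K, V, d, vis)
        assert np.abs(out - ref_out).max() < 1e-6
        assert np.abs(w - ref_w).max() < 1e-6
        assert (w[~vis] == 0.0).all()


def test_attention_all_forbidden_row_errors():
    vis = np.array([[True, False], [False, False]])
    with pytest.raises(ValueError, match="no position"):
        scaled_attention(np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)),
                         visibility=vis)


def test_forward_shapes_and_row_sums(tiny_config, tiny_params, vocab):
    ids = np.array([[1, 2, 3, 4, vocab.pad_id]])
    vis = pretrain_visibility(np.array([4]), 5)
    feats, maps = encoder_forward(ids, tiny_config, tiny_params, vis)
    assert feats.shape == (1, 5, tiny_config.embed_size)
    assert len(maps) == tiny_config.n_layers
    for m in maps:
        assert m.shape == (1, tiny_config.n_heads, 5, 5)
        assert np.allclose(m.sum(axis=-1), 1.0)
        assert (m[0, :, :4, 4] == 0.0).all()  # pads receive no attention


def test_pad_invariance(tiny_config, tiny_params, vocab):
    ids = np.array([[1, 2, 3, 4]])
    vis = pretrain_visibility(np.array([4]), 4)
    feats_a, _ = encoder_forward(ids, tiny_config, tiny_params, vis)
    ids_b = np.concatenate([ids, np.full((1, 8), vocab.pad_id)], axis=1)
    vis_b = pretrain_visibility(np.array([4]), 12)
    feats_b, _ = encoder_forward(ids_b, tiny_config, tiny_params, vis_b)
    assert np.abs(feats_a.data[0, :4] - feats_b.data[0, :4]).max() < 1e-6


def test_masking_soundness(tiny_config, tiny_params):
    """Perturbing an embedding no row may attend to leaves outputs unchanged."""
    ids = np.array([[1, 2, 3]])
    vis = np.ones((3, 3), dtype=bool)
    vis[:, 2] = False
    vis[2, 2] = True  # only position 2 sees itself
    base, _ = encoder_forward(ids, tiny_config, tiny_params, vis)
    tiny_params["embed"].data[3] += 10.0
    pert, _ = encoder_forward(ids, tiny_config, tiny_params, vis)
    tiny_params["embed"].data[3] -= 10.0
    assert np.abs(base.data[0, :2] - pert.data[0, :2]).max() < 1e-12


def test_medium_preset_feature_width(vocab):
    config = ModelConfig.preset("medium", vocab_size=vocab.size)
    assert (config.n_layers, config.n_heads) == (8, 8)
    assert config.embed_size == 256 and config.ffn_size == 1024
    params = init_parameters(config, np.random.default_rng(0))
    ids = np.random.default_rng(1).integers(0, 40, size=(1, 10))
    vis = pretrain_visibility(np.array([10]), 10)
    feats, _ = encoder_forward(ids, config, params, vis)
    assert feats.shape == (1, 10, 256)


def test_preset_table():
    assert PRESETS["small"] == (4, 4, 128, 512)
    assert PRESETS["large"] == (12, 12, 576, 2304)
    with pytest.raises(ValueError):
        ModelConfig.preset("huge", vocab_size=10)
    with pytest.raises(ValueError):
        ModelConfig(2, 3, 32, 64, vocab_size=10)  # 32 % 3 != 0


def test_checkpoint_round_trip(tiny_config, tiny_params, tmp_path):
    path = tmp_path / "ck.npz"
    save_checkpoint(path, tiny_config, tiny_params, extra={"note": "x"})
    config, params, extra = load_checkpoint(path)
    assert config == tiny_config
    assert extra["note"] == "x"
    for k, t in tiny_params.items():
        assert np.array_equal(t.data, params[k].data)


def test_checkpoint_validates_shapes(tiny_config, tiny_params, tmp_path):
    path = tmp_path / "bad.npz"
    tiny_params["layers.0.wq"].data = np.zeros((2, 2))
    save_checkpoint(path, tiny_config, tiny_params)
    with pytest.raises(ValueError, match="wq"):
        load_checkpoint(path)
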