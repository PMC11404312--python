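import numpy as np
import pytest

from smibert import (compute_metrics, export_token_embeddings,
                     extract_task_attention, predict_with_fusion,
                     task_correlation)


def test_fusion_is_arithmetic_mean(tiny_finetuned):
    res = predict_with_fusion(tiny_finetuned, "CC(=O)Oc1ccccc1",
                              n_variants=6, seed=0)
    assert res.per_variant.shape[1] == 3
    assert np.allclose(res.per_task, res.per_variant.mean(axis=0))
    # fused classification probability bounded by the per-variant range
    for t in (0, 1):
        col = res.per_variant[:, t]
        assert col.min() - 1e-12 <= res.per_task[t] <= col.max() + 1e-12
        assert 0.0 <= res.per_task[t] <= 1.0


def test_fusion_single_variant_is_identity(tiny_finetuned):
    res = predict_with_fusion(tiny_finetuned, "CCO", n_variants=1, seed=0)
    assert res.per_variant.shape[0] == 1
    assert np.allclose(res.per_task, res.per_variant[0])


def test_fusion_unique_form_molecule(tiny_finetuned):
    res = predict_with_fusion(tiny_finetuned, "C", n_variants=20, seed=0)
    assert res.per_variant.shape[0] == 1


def test_fusion_median_flag(tiny_finetuned):
    res = predict_with_fusion(tiny_finetuned, "CCOc1ccccc1", n_variants=5,
                              seed=0, fusion="median")
    assert np.allclose(res.per_task, np.median(res.per_variant, axis=0))
    with pytest.raises(ValueError):
        predict_with_fusion(tiny_finetuned, "CCO", fusion="max")


def test_fusion_reduces_variance(tiny_finetuned):
    """Across enumeration seeds, fused predictions vary less than raw
    single-rendering predictions."""
    fused, singles = [], []
    for seed in range(15):
        res = predict_with_fusion(tiny_finetuned, "CC(=O)Oc1ccccc1CN",
                                  n_variants=8, seed=seed)
        fused.append(res.per_task[2])
        singles.extend(res.per_variant[1:, 2])  # non-canonical renderings
    assert np.var(fused) <= np.var(singles) + 1e-12


def test_regression_output_is_unscaled(tiny_finetuned):
    # scaler (mean 2, std 3) is inverted: outputs live on the label scale
    res = predict_with_fusion(tiny_finetuned, "CCO", n_variants=1, seed=0)
    from smibert.multitask import build_multitask_batch, multitask_forward
    from smibert.datasets import MoleculeRecord
    rec = MoleculeRecord("CCO", np.zeros(3), np.zeros(3, bool))
    batch = build_multitask_batch([rec], tiny_finetuned.vocab, 3)
    raw = multitask_forward(batch, tiny_finetuned.config,
                            tiny_finetuned.params, tiny_finetuned.heads)
    assert res.per_task[2] == pytest.approx(raw[2].data[0] * 3.0 + 2.0)


def test_metrics_match_explicit_formulas():
    y = np.array([[1.0], [0.0], [1.0], [0.0]])
    p = np.array([[0.9], [0.2], [0.7], [0.4]])
    obs = np.ones((4, 1), dtype=bool)
    rep = compute_metrics(p, y, obs, ["classification"], ["t"])
    assert rep["t"]["accuracy"] == 1.0
    assert rep["t"]["roc_auc"] == 1.0
    # regression on a hand-picked 4-point set
    yr = np.array([[1.0], [2.0], [3.0], [4.0]])
    pr = np.array([[1.1], [1.9], [3.2], [3.8]])
    rep = compute_metrics(pr, yr, obs, ["regression"], ["r"])
    rmse = np.sqrt(np.mean((yr - pr) ** 2))
    ss_res = np.sum((yr - pr) ** 2)
    ss_tot = np.sum((yr - yr.mean()) ** 2)
    assert rep["r"]["rmse"] == pytest.approx(rmse)
    assert rep["r"]["r2"] == pytest.approx(1 - ss_res / ss_tot)


def test_metrics_constant_score_auc_half():
    y = np.array([[1.0], [0.0], [1.0], [0.0]])
    p = np.full((4, 1), 0.5)
    rep = compute_metrics(p, y, np.ones((4, 1), bool), ["classification"])
    assert rep["task0"]["roc_auc"] == pytest.approx(0.5)


def test_metrics_undefined_cases_flagged():
    y = np.array([[1.0], [1.0]])
    p = np.array([[0.6], [0.7]])
    rep = compute_metrics(p, y, np.ones((2, 1), bool), ["classification"])
    assert rep["task0"]["roc_auc"] is None  # single class present
    rep2 = compute_metrics(p, y, np.zeros((2, 1), bool), ["regression"])
    assert rep2["task0"]["rmse"] is None and rep2["task0"]["n_observed"] == 0


def test_perfect_predictions_metrics():
    y = np.array([[1.0, 2.0], [0.0, 5.0]])
    obs = np.ones((2, 2), dtype=bool)
    rep = compute_metrics(y, y, obs, ["classification", "regression"])
    assert rep["task0"]["accuracy"] == 1.0
    assert rep["task1"]["r2"] == 1.0 and rep["task1"]["rmse"] == 0.0


def test_task_attention_is_a_softmax_row(tiny_finetuned):
    amap = extract_task_attention(tiny_finetuned, "CC(=O)Oc1ccccc1", 1)
    assert len(amap.weights) == len(amap.tokens.tokens)
    assert (amap.weights >= 0).all()
    assert amap.weights.sum() + amap.self_weight == pytest.approx(1.0)
    assert amap.task_name == "clf_b"


def test_task_attention_single_token(tiny_finetuned):
    amap = extract_task_attention(tiny_finetuned, "C", 0)
    assert len(amap.weights) == 1
    assert amap.weights[0] + amap.self_weight == pytest.approx(1.0)


def test_task_attention_ignores_other_heads(tiny_finetuned):
    from smibert.multitask import FinetunedModel
    m = tiny_finetuned
    swapped = FinetunedModel(m.config, m.params, m.vocab,
                             [m.heads[0], m.heads[2], m.heads[1]],
                             [m.scalers[0], m.scalers[2], m.scalers[1]])
    a = extract_task_attention(m, "CCOc1ccccc1", 0)
    b = extract_task_attention(swapped, "CCOc1ccccc1", 0)
    assert np.allclose(a.weights, b.weights)
    with pytest.raises(IndexError):
        extract_task_attention(m, "CCO", 5)


def test_task_correlation_properties(tiny_finetuned, corpus50):
    corr, order = task_correlation(tiny_finetuned, corpus50[:6])
    assert corr.shape == (3, 3)
    assert np.allclose(np.diag(corr), 1.0)
    finite = np.isfinite(corr)
    assert np.allclose(corr[finite], corr.T[finite])
    assert np.nanmin(corr) >= -1.0 - 1e-9 and np.nanmax(corr) <= 1.0 + 1e-9
    assert sorted(order) == [0, 1, 2]
    with pytest.raises(ValueError):
        task_correlation(tiny_finetuned, [])


def test_token_embedding_export(tiny_encoder_model):
    df = export_token_embeddings(tiny_encoder_model, ["CCOCC", "bad(((", "CO"])
    width = tiny_encoder_model.config.embed_size
    assert [c for c in df.columns if c.startswith("f")] == \
        [f"f{i}" for i in range(width)]
    assert (df["molecule_id"] == 0).sum() == 5
    assert (df["molecule_id"] == 2).sum() == 2
    assert df.attrs["skipped"] and df.attrs["skipped"][0][0] == 1
    df2 = export_token_embeddings(tiny_encoder_model, ["CCOCC"])
    assert np.allclose(df[df.molecule_id == 0].filter(like="f").values,
                       df2.filter(like="f").values)
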