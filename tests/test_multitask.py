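import numpy as np
import pytest

from smibert import (EarlyStopping, build_multitask_batch, finetune_loop,
                     multitask_forward, multitask_loss)
from smibert.autodiff import Tensor
from smibert.datasets import MoleculeRecord, TaskTable
from smibert.multitask import (_apply_scalers, fit_scalers,
                               load_finetuned, save_finetuned)
from smibert.pretrain import EncoderModel


def _recs(smiles_list, n_tasks=2):
    return [MoleculeRecord(s, np.zeros(n_tasks), np.ones(n_tasks, bool))
            for s in smiles_list]


def test_batch_visibility_rule_counts(vocab):
    # T=2 tasks, one 3-token molecule, no padding:
    # task rows see self + 3 SMILES; SMILES rows see 3 SMILES positions
    batch = build_multitask_batch(_recs(["CCO"]), vocab, n_tasks=2)
    counts = batch.visibility[0].sum(axis=1).tolist()
    assert counts == [4, 4, 3, 3, 3]
    # no SMILES row may see any task column
    assert not batch.visibility[0, 2:, :2].any()
    # no task row sees the other task
    assert not batch.visibility[0, 0, 1] and not batch.visibility[0, 1, 0]
    # positional encoding excluded exactly at task slots
    assert batch.positional_mask.tolist() == [False, False, True, True, True]


def test_batch_padding_rows(vocab):
    batch = build_multitask_batch(_recs(["CCO", "C"]), vocab, n_tasks=1)
    # second row: 1 real token, 2 pads; pad rows self-only
    assert batch.input_ids[1, 2] == vocab.pad_id
    assert batch.visibility[1, 2].sum() == 1 and batch.visibility[1, 2, 2]
    # task row of the short molecule sees self + 1 real token only
    assert batch.visibility[1, 0].sum() == 2


def test_batch_capacity_error(vocab):
    with pytest.raises(ValueError, match="task tokens"):
        build_multitask_batch(_recs(["C"], n_tasks=1), vocab,
                              n_tasks=vocab.n_task_tokens + 1)


def test_forward_shapes(tiny_finetuned):
    m = tiny_finetuned
    batch = build_multitask_batch(_recs(["CCO", "CCN", "c1ccccc1", "CC"],
                                        n_tasks=3), m.vocab, 3)
    preds = multitask_forward(batch, m.config, m.params, m.heads)
    assert preds[0].shape == (4, 2)   # classification logits
    assert preds[2].shape == (4,)     # regression values
    with pytest.raises(ValueError, match="heads"):
        multitask_forward(batch, m.config, m.params, m.heads[:2])


def test_task_slot_permutation_invariance(tiny_finetuned):
    """Task tokens carry no positional encoding and never attend to each
    other, so reordering slots (with heads reordered too) changes nothing."""
    m = tiny_finetuned
    recs = _recs(["CC(=O)Oc1ccccc1", "CCO"], n_tasks=3)
    perm = [2, 0, 1]
    base = multitask_forward(build_multitask_batch(recs, m.vocab, 3),
                             m.config, m.params, m.heads)
    permuted = multitask_forward(
        build_multitask_batch(recs, m.vocab, 3, task_token_order=perm),
        m.config, m.params, [m.heads[t] for t in perm])
    for slot, t in enumerate(perm):
        assert np.abs(permuted[slot].data - base[t].data).max() < 1e-10


def test_cross_task_head_gradients_exactly_zero(tiny_finetuned):
    m = tiny_finetuned
    batch = build_multitask_batch(_recs(["CCO", "CCN"], n_tasks=3), m.vocab, 3)
    preds = multitask_forward(batch, m.config, m.params, m.heads)
    labels = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 1.0]])
    observed = np.zeros((2, 3), dtype=bool)
    observed[:, 0] = True  # only task 0 observed
    loss = multitask_loss(preds, labels, observed, m.task_kinds)
    loss.backward()
    assert all(p.grad is not None and np.abs(p.grad).sum() > 0
               for p in m.heads[0].parameters())
    for other in (1, 2):
        assert all(p.grad is None for p in m.heads[other].parameters())
    for h in m.heads:
        for p in h.parameters():
            p.grad = None


def test_loss_arithmetic_against_hand_computation():
    # 2 molecules, 2 tasks: classification logits + regression values
    logits = Tensor(np.array([[2.0, 0.0], [0.0, 1.0]]))
    values = Tensor(np.array([1.5, -0.5]))
    labels = np.array([[1.0, 2.0], [0.0, 1.0]])
    observed = np.array([[True, True], [True, False]])
    loss = multitask_loss([logits, values], labels, observed,
                          ["classification", "regression"])
    # classification: -log softmax picked per molecule, averaged
    def nll(z, y):
        e = np.exp(z - z.max())
        return -np.log(e[y] / e.sum())
    clf = (nll(np.array([2.0, 0.0]), 1) + nll(np.array([0.0, 1.0]), 0)) / 2
    reg = (1.5 - 2.0) ** 2  # only the observed cell
    assert loss.item() == pytest.approx(clf + reg, abs=1e-12)


def test_loss_edge_cases():
    values = Tensor(np.array([2.0, 1.0]))
    labels = np.array([[2.0], [1.0]])
    assert multitask_loss([values], labels, np.ones((2, 1), bool),
                          ["regression"]).item() == 0.0
    with pytest.raises(ValueError, match="no observed"):
        multitask_loss([values], labels, np.zeros((2, 1), bool), ["regression"])


def test_unobserved_task_contributes_nothing(tiny_finetuned):
    """Adding records fully unobserved for a task leaves its loss term 0."""
    m = tiny_finetuned
    batch = build_multitask_batch(_recs(["CCO"], n_tasks=3), m.vocab, 3)
    preds = multitask_forward(batch, m.config, m.params, m.heads)
    observed = np.array([[True, False, False]])
    labels = np.array([[1.0, 1.0, 5.0]])
    full = multitask_loss(preds, labels, observed, m.task_kinds)
    only0 = multitask_loss([preds[0]], labels[:, :1], observed[:, :1],
                           m.task_kinds[:1])
    assert full.item() == pytest.approx(only0.item(), abs=1e-12)


def test_early_stopping_patience_arithmetic():
    # flat validation loss from epoch 1 stops after epoch 21
    s = EarlyStopping(patience=20)
    stopped_at = None
    for epoch in range(1, 200):
        if s.update(1.0, epoch):
            stopped_at = epoch
            break
    assert stopped_at == 21
    # strictly improving loss never stops
    s2 = EarlyStopping(patience=20)
    assert not any(s2.update(1.0 / e, e) for e in range(1, 201))
    assert s2.best_epoch == 200


def test_finetune_stops_at_21_on_flat_validation(tiny_encoder_model,
                                                 monkeypatch):
    import smibert.multitask as mt
    monkeypatch.setattr(mt, "_validation_loss",
                        lambda *a, **k: 1.0)
    table = _tiny_table()
    _, log = finetune_loop(tiny_encoder_model, table, lr=1e-3, batch_size=8,
                           max_epochs=200, patience=20, dropout_rate=0.0,
                           seed=0)
    assert len(log) == 21


def test_finetune_runs_to_max_epochs_when_improving(tiny_encoder_model,
                                                    monkeypatch):
    import smibert.multitask as mt
    state = {"v": 10.0}

    def improving(*a, **k):
        state["v"] *= 0.9
        return state["v"]

    monkeypatch.setattr(mt, "_validation_loss", improving)
    _, log = finetune_loop(tiny_encoder_model, _tiny_table(), lr=1e-3,
                           batch_size=8, max_epochs=6, patience=3,
                           dropout_rate=0.0, seed=0)
    assert len(log) == 6


def _tiny_table():
    smiles = ["CCO", "CCN", "CCC", "CCCC", "c1ccccc1", "CCOC",
              "CC(=O)O", "CCS", "CCCO", "CCCN", "CC", "CCCCO"]
    recs = []
    for i, s in enumerate(smiles):
        recs.append(MoleculeRecord(
            s, np.array([float(i % 2)]), np.array([True]),
            split="train" if i < 8 else ("valid" if i < 10 else "test")))
    return TaskTable(["parity"], ["classification"], recs)


def test_finetune_restores_best_weights(tiny_encoder_model, monkeypatch):
    """The returned model reproduces the best-validation epoch, not the last."""
    import smibert.multitask as mt
    seq = iter([3.0, 1.0, 2.0, 2.5, 2.6])
    monkeypatch.setattr(mt, "_validation_loss", lambda *a, **k: next(seq))
    model, log = finetune_loop(tiny_encoder_model, _tiny_table(), lr=1e-2,
                               batch_size=8, max_epochs=5, patience=3,
                               dropout_rate=0.0, seed=0)
    assert min(e["valid_loss"] for e in log) == 1.0


def test_scalers_round_trip(two_task_table):
    scalers = fit_scalers(two_task_table)
    assert scalers[0] is None  # classification task untouched
    mu, sd = scalers[1]
    assert sd > 0
    labels = np.array([[0.0, 3.0], [1.0, 7.0]])
    z = _apply_scalers(labels, two_task_table.task_kinds, scalers)
    assert np.allclose(z[:, 0], labels[:, 0])
    assert np.allclose(z[:, 1] * sd + mu, labels[:, 1])


def test_save_load_finetuned_predictions_identical(tiny_finetuned, tmp_path):
    from smibert.inference import predict_with_fusion
    path = tmp_path / "ft.npz"
    save_finetuned(path, tiny_finetuned)
    loaded = load_finetuned(path)
    a = predict_with_fusion(tiny_finetuned, "CC(=O)Oc1ccccc1", 4, seed=1)
    b = predict_with_fusion(loaded, "CC(=O)Oc1ccccc1", 4, seed=1)
    assert np.allclose(a.per_task, b.per_task)
    assert loaded.task_names == tiny_finetuned.task_names
    assert loaded.scalers == tiny_finetuned.scalers


def test_learnability_on_separable_labels(vocab, tiny_config, corpus50):
    """Noise-free token-statistic labels are learnable: training loss falls
    by an order of magnitude on a tiny encoder."""
    from smibert import (contains_token_rule, generate_task_table,
                         split_table, token_count_rule)
    from smibert.encoder import init_parameters
    table = split_table(
        generate_task_table(corpus50,
                            [contains_token_rule("c"), token_count_rule("O")],
                            seed=1), seed=2)
    pre = EncoderModel(tiny_config,
                       init_parameters(tiny_config, np.random.default_rng(0)),
                       vocab)
    _, log = finetune_loop(pre, table, lr=1e-3, batch_size=16, max_epochs=40,
                           patience=40, dropout_rate=0.0, seed=0)
    assert log[0]["train_loss"] / log[-1]["train_loss"] >= 10.0
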