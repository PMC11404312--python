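"""Fusion prediction and attention interpretability.

Prediction enumerates several SMILES renderings of the molecule, predicts
each, and averages (classification: class-1 probability; regression: the
un-z-scored value). Interpretability reads the fine-tuned model's attention
row of a task token over the SMILES tokens: high weight = high contribution
to that task's molecular representation. Task similarity is the average
Pearson correlation between tasks' attention-weight vectors.
"""

import numpy as np

from smibert import (FixtureSpec, ModelConfig, build_vocabulary,
                     contains_token_rule, extract_task_attention,
                     finetune_loop, generate_corpus, generate_task_table,
                     predict_with_fusion, split_table, task_correlation,
                     token_count_rule)
from smibert.encoder import init_parameters
from smibert.pretrain import EncoderModel

vocab = build_vocabulary(n_task_tokens=16)
corpus = generate_corpus(FixtureSpec(n_molecules=120, seed=5))
table = split_table(
    generate_task_table(corpus, [contains_token_rule("c"),
                                 token_count_rule("O")], seed=1), seed=2)
config = ModelConfig(n_layers=2, n_heads=2, embed_size=32, ffn_size=64,
                     dropout_rate=0.0, vocab_size=vocab.size)
model, _ = finetune_loop(
    EncoderModel(config, init_parameters(config, np.random.default_rng(0)), vocab),
    table, lr=1e-3, batch_size=32, max_epochs=45, patience=45,
    dropout_rate=0.0, seed=0)

smiles = "CCOc1ccccc1"
res = predict_with_fusion(model, smiles, n_variants=10, seed=4)
print(f"{smiles}: {res.per_variant.shape[0]} renderings predicted")
print(f"  P(aromatic)   fused = {res.per_task[0]:.3f}  "
      f"(per-rendering range {res.per_variant[:, 0].min():.3f}"
      f"..{res.per_variant[:, 0].max():.3f})")
print(f"  oxygen count  fused = {res.per_task[1]:.2f}  (true count: 1)")

amap = extract_task_attention(model, smiles, task_index=1)
print(f"\nattention of task '{amap.task_name}' (layer {amap.layer}):")
for tok, w in zip(amap.tokens.tokens, amap.weights):
    print(f"  {tok:>3} {'#' * int(40 * w)} {w:.3f}")

corr, order = task_correlation(model, corpus[:10])
print(f"\ntask attention correlation:\n{np.round(corr, 3)}")
print(f"dendrogram leaf order: {order}")
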