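# Methods

## Overview

`smibert` implements a three-stage transfer-learning pipeline for
molecular property prediction from SMILES text: (1) self-supervised
pretraining of a Transformer encoder by masked-token recovery on unlabeled
molecules, (2) multitask fine-tuning in which every property task owns a
reserved *task token* whose encoder output feeds a per-task head, and
(3) prediction with test-time SMILES-enumeration fusion. The assumptions
are those of the underlying recipe: that SMILES syntax carries enough
contextual signal for a masked language model to learn chemically
meaningful token representations, that related property tasks share
structure a common encoder can exploit, and that averaging predictions
over renderings of the same molecule cancels rendering-specific bias.

## Tokenization and vocabulary

The tokenizer is a single ordered-alternation regular expression: the
two-letter element symbols `Si Mg Ca Fe As Al Cl Br` first (so they can
never be split), then a character class covering digits, branch/charge
punctuation, `=` and `:` bonds, `@`, brackets and the
organic-subset/aromatic letters, then `/` and `\`. Scanning is
leftmost-longest and total: a character matched by no alternative raises
an error with its position, because silently dropping text would
desynchronize tokens from labels downstream. The vocabulary is the fixed
enumeration of all matchable tokens, then `[MASK]`, `[PAD]`, then
`n_task_tokens` task tokens (default 1000, configurable); ids are
contiguous and the token↔id maps are exact inverses. One plain-text file,
one token per line, serializes it.

## Encoder

Token ids index an embedding dictionary **D** ∈ R^{V×F}; embeddings are
multiplied by √F before the fixed sinusoidal positional encoding is added,
so the O(1)-magnitude encoding does not dominate the 0.02-scale embedding
initialization. Each of the `n_layers` blocks applies multi-head scaled
dot-product self-attention (per-head width d_k = F/H, scaling 1/√d_k),
then a two-layer position-wise FFN with exact GELU, each sublayer followed
by a residual add and layer normalization (post-norm ordering). Dropout
(default rate 0.1) is applied to attention weights, the attention output
and the FFN output during training.

Attention is restricted by a boolean *visibility* matrix converted to an
additive −∞ bias before the softmax, so forbidden pairs receive exactly
zero weight and zero gradient. Padding positions are always forbidden to
real rows (and see only themselves, keeping every softmax row valid),
which makes outputs at real positions exactly invariant to the amount of
trailing padding — a property the tests assert at 1e−6.

Size presets (layers, heads, F, FFN): small (4, 4, 128, 512), medium
(8, 8, 256, 1024), large (12, 12, 576, 2304). `max_sequence_length`
defaults to 200 tokens.

## Pretraining objective

Per molecule, `max(1, round(0.15·n))` distinct positions are selected
uniformly (round half up; the floor guarantees at least one selection for
short strings). Each selected position independently becomes `[MASK]` with
probability 0.8, a uniformly random *chemical* token with probability 0.1
(specials and task tokens are never drawn), or stays unchanged with
probability 0.1. Cross-entropy is averaged over selected positions only;
gradients at unselected positions are exactly zero. Corruption is
re-sampled fresh every epoch. Recovery accuracy — argmax correctness at
selected positions — is the evaluation metric, optionally averaged over
several corruption draws for lower variance.

Reference defaults: Adam, learning rate 1e−4, batch 512, 50 epochs, 10%
of the corpus held out for evaluation. For desk-scale corpora (tens to
hundreds of molecules) the package's recipe is lr 1e−3 with 5% linear
warmup and cosine decay (`lr_schedule="cosine"`), global gradient-norm
clipping at 1.0, and dropout 0 when the goal is a memorization/capacity
check — without clipping, early loss spikes of the post-norm stack
destabilize Adam at these learning rates.

## Multitask fine-tuning

Input rows are `[T0] … [T(T−1)]` followed by SMILES ids and padding.
Visibility rules: task rows attend to themselves and to real SMILES
positions (not to other tasks, not to pads); SMILES rows attend to real
SMILES positions only (never to task tokens — the input distribution the
encoder saw in pretraining is preserved); pad rows attend to themselves.
Positional encoding is added to SMILES positions only. Together these
make task slots exchangeable: permuting task tokens and heads consistently
leaves every prediction unchanged, and cross-task head gradients are
exactly zero — both asserted by tests.

Each task owns a 2-layer head (hidden width F, GELU, dropout) emitting 2
logits (classification) or 1 value (regression). Regression labels are
z-scored per task on the training split (the scaler is stored in the
checkpoint and inverted at prediction). The total loss is the unweighted
sum over tasks of the per-task loss averaged over that task's observed
labels in the batch; a task with no observed label in a batch contributes
exactly zero. Training follows the train split of an 8:1:1 per-source
random split (augmentation happens strictly after splitting, so enumerated
renderings inherit their parent's split and cannot leak); the validation
split drives early stopping (patience 20 epochs, maximum 200, best
weights restored). Reference defaults: Adam, lr 5e−5, batch 64, dropout
0.1; desk-scale runs use lr 1e−3.

## Enumeration and fusion

Enumeration draws random atom orderings with RDKit and keeps renderings
not seen before for the molecule; the canonical SMILES is always variant
#1, and a slot gives up after 100 consecutive duplicate draws, so
single-rendering molecules like methane yield one variant without error.
Every variant must canonicalize back to the input — the equivalence oracle
used throughout the tests. Dataset augmentation (default factor 20) copies
labels, observed-masks and split verbatim onto each rendering and shuffles
deterministically. At prediction time the per-rendering outputs
(class-1 probabilities; un-z-scored regression values) are fused by
arithmetic mean (median behind a flag); the fused probability necessarily
lies within the per-rendering range.

## Interpretability

The attention row of task *t* over SMILES positions — last layer by
default, averaged over heads, layer selectable — is the per-token
contribution weight to that task's molecular representation; with the
task's self-weight it sums to 1. Task similarity is the Pearson
correlation between two tasks' weight vectors, computed per molecule and
averaged over a sample (pairs with constant vectors are skipped; entries
with no defined value are NaN), followed by average-linkage hierarchical
clustering on 1 − correlation.

## Synthetic data

The fixture generator assembles molecules from valence-safe fragments —
alkyl units, ether/amine/thioether links, carbonyl/ester/amide groups,
benzene and cycloalkane ring prefixes, terminal halogens — with weights
that keep heavy atoms mostly carbon and rings frequent, as in drug-like
libraries; candidates are validated with RDKit and deduplicated by
canonical form, so every corpus is a set of real parseable molecules.
Labels are deterministic functions of token statistics (e.g. the count of
`O` tokens, presence of aromatic `c`) plus optional Gaussian noise, which
makes ground truth recoverable by the tokenizer itself and learnability
checks self-contained. What these fixtures do **not** emulate: realistic
property distributions, stereochemistry, charged/bracket atoms, large
rings, or inter-task label correlations of real ADMET panels — so passing
tests demonstrate the mechanics and invariants of the method, not
chemical accuracy on real data.

## Numerical implementation

All training runs on `smibert.autodiff`, a reverse-mode automatic
differentiation engine over float64 NumPy arrays (broadcasting
arithmetic, batched matmul, stable masked softmax/log-softmax, layer
norm, exact GELU, embedding lookup with scatter-add backward, inverted
dropout); analytic gradients are verified against central finite
differences in the test suite. Optimization is Adam (β₁ 0.9, β₂ 0.999,
ε 1e−8) with global gradient-norm clipping (default 1.0). Weight
initialization is N(0, 0.02) for matrices, zeros for biases, ones for
layer-norm scales. A non-finite pretraining loss aborts the run and
restores the last epoch-end weights. Checkpoints are single `.npz`
archives carrying a format version, the config, every parameter array and
JSON metadata (vocabulary, task names/kinds, label scalers); loading
validates shapes against the config.

## Problem sizes used in the shipped studies

The test suite and acceptance script run everything at desk scale, chosen
as the smallest sizes that still exercise every mechanism: 50-molecule
corpora for memorization pretraining (small preset, 200 epochs, batch 16),
a 200-molecule two-task table for learnability and held-out evaluation
(40 epochs), and 2-layer/32-wide encoders for pure mechanics tests. At
the 800 gradient steps the memorization study comprises, recovery
accuracy on the training corpus reaches ≈0.89 and is still rising
(≈0.93 by epoch 500); the capacity is there, but full memorization needs
more steps than that budget provides.

## Known limitations

* CPU-only NumPy training: throughput is adequate for desk-scale studies,
  not for millions of molecules.
* The tokenizer's character class covers the common organic subset; exotic
  elements outside the listed alternatives are (deliberately) errors.
* Regression heads assume roughly unimodal label distributions; only
  per-task z-scoring is provided.
* The task-correlation analysis reads attention weights, not causal
  attributions; it is a similarity heuristic.
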