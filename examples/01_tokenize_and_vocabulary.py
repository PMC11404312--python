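"""Tokenize SMILES strings and build the model vocabulary.

The tokenizer applies a fixed regular expression: two-letter element
symbols (Cl, Br, Si, ...) stay whole, every other matched character is its
own token, and any unmatchable character is an error rather than being
silently dropped.
"""

from smibert import build_vocabulary, encode, decode, tokenize

for smiles in ["CCO", "c1ccccc1Cl", "CC(=O)Oc1ccccc1C(=O)O", "[nH]"]:
    seq = tokenize(smiles)
    print(f"{smiles:>24} -> {list(seq.tokens)}")

vocab = build_vocabulary(n_task_tokens=1000)
print(f"\nvocabulary size V = {vocab.size} "
      f"(chemical tokens + [MASK] + [PAD] + 1000 task tokens)")

ids = encode(tokenize("CCO"), vocab)
print(f"'CCO' -> ids {ids} -> tokens {decode(ids, vocab)}")
# Each id indexes a row of the learned embedding dictionary D in R^{V x F};
# the round trip shows the token <-> id bijection is lossless.
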