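import numpy as np
import pytest

from smibert import (FixtureSpec, ModelConfig, build_vocabulary,
                     contains_token_rule, generate_corpus,
                     generate_task_table, split_table, token_count_rule)
from smibert.encoder import init_parameters
from smibert.multitask import FinetunedModel, TaskHead
from smibert.pretrain import EncoderModel


@pytest.fixture(scope="session")
def vocab():
    return build_vocabulary(n_task_tokens=16)


@pytest.fixture(scope="session")
def tiny_config(vocab):
    # 2 layers / 2 heads / width 32: big enough to exercise every code path,
    # small enough for sub-second forward passes
    return ModelConfig(n_layers=2, n_heads=2, embed_size=32, ffn_size=64,
                       dropout_rate=0.0, vocab_size=vocab.size)


@pytest.fixture()
def tiny_params(tiny_config):
    return init_parameters(tiny_config, np.random.default_rng(0))


@pytest.fixture(scope="session")
def corpus50():
    return generate_corpus(FixtureSpec(n_molecules=50, seed=11))


@pytest.fixture(scope="session")
def two_task_table(corpus50):
    rules = [contains_token_rule("c"), token_count_rule("O")]
    table = generate_task_table(corpus50, rules, seed=1)
    return split_table(table, seed=2)


@pytest.fixture(scope="session")
def tiny_finetuned(vocab):
    """A random-weight 3-task model: exercises prediction/attention paths
    without any training."""
    config = ModelConfig(n_layers=2, n_heads=2, embed_size=32, ffn_size=64,
                         dropout_rate=0.0, vocab_size=vocab.size)
    rng = np.random.default_rng(3)
    params = init_parameters(config, rng)
    heads = [
        TaskHead.create("clf_a", "classification", 32, rng),
        TaskHead.create("clf_b", "classification", 32, rng),
        TaskHead.create("reg_c", "regression", 32, rng),
    ]
    scalers = [None, None, (2.0, 3.0)]
    return FinetunedModel(config, params, vocab, heads, scalers)


@pytest.fixture()
def tiny_encoder_model(tiny_config, tiny_params, vocab):
    return EncoderModel(tiny_config, tiny_params, vocab)
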