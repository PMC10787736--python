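import numpy as np
import pytest

from npnamematch import pairgen, siamese


@pytest.fixture(scope="session")
def small_lexicon():
    """A 6-group synthetic lexicon shared by fast tests."""
    return pairgen.synth_lexicon(6, seed=11)


@pytest.fixture(scope="session")
def toy_model():
    """A small untrained model for contract tests (fast to evaluate)."""
    config = siamese.ModelConfig(
        embed_hidden=16, embed_dim=8, recurrent_units=8, seed=3
    )
    return siamese.build_model(config)


@pytest.fixture(scope="session")
def trained_toy():
    """A small model trained on a 6-group dataset until it separates pairs.

    Used by every test that needs a *trained* distance; kept small so the
    whole session trains it once in a few seconds.
    """
    lexicon = pairgen.synth_lexicon(6, seed=11)
    config = pairgen.PerturbationConfig(rng_seed=11)
    data = pairgen.build_dataset(
        lexicon, config, pairs_per_group=60, holdout_n=200, seed=11
    )
    model_config = siamese.ModelConfig(
        embed_hidden=32,
        embed_dim=16,
        recurrent_units=16,
        batch_size=128,
        max_epochs=40,
        patience=5,
        seed=11,
    )
    model = siamese.build_model(model_config)
    model, history = siamese.train(model, data, model_config)
    return {"model": model, "history": history, "data": data, "lexicon": lexicon}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
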