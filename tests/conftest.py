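"""Shared fixtures: toy corpora and trained/untrained models.

The two trained models (identity copy task and Cl->Br halogen swap) are
expensive, so they are built once per session and shared by the model,
decoding and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from seqhop import fixtures
from seqhop.model import ModelConfig, Seq2Seq, Seq2SeqResults
from seqhop.nn import init_params


def make_untrained_results(pairs, seed: int = 0, config: ModelConfig | None = None
                           ) -> Seq2SeqResults:
    """Results object with freshly initialised (untrained) parameters."""
    cfg = config or ModelConfig.tiny(epochs=1)
    model = Seq2Seq(pairs, config=cfg)
    rng = np.random.default_rng(seed)
    params = init_params(
        len(model.vocab), cfg.model_width, cfg.heads, cfg.ff_width,
        cfg.encoder_layers, cfg.decoder_layers, cfg.max_positions, rng,
    )
    hist = pd.DataFrame(columns=["epoch", "train_nll", "valid_nll"])
    return Seq2SeqResults(model.net, model.vocab, cfg, params, hist, 0, seed)


@pytest.fixture(scope="session")
def grammar_molecules():
    return fixtures.make_smiles_set(100, seed=101)


@pytest.fixture(scope="session")
def identity_corpus():
    df = fixtures.make_pair_corpus("identity", 550, seed=7)
    return list(zip(df.source, df.target))


@pytest.fixture(scope="session")
def halogen_corpus():
    df = fixtures.make_pair_corpus("halogen_swap", 550, seed=11)
    return list(zip(df.source, df.target))


@pytest.fixture(scope="session")
def identity_results(identity_corpus):
    """Tiny model trained on the 500-pair identity (copy) task."""
    model = Seq2Seq(identity_corpus[:500], identity_corpus[500:],
                    config=ModelConfig.tiny())
    return model.fit(seed=1)


@pytest.fixture(scope="session")
def halogen_results(halogen_corpus):
    """Tiny model trained on the 500-pair Cl->Br swap rule."""
    model = Seq2Seq(halogen_corpus[:500], halogen_corpus[500:],
                    config=ModelConfig.tiny())
    return model.fit(seed=2)


@pytest.fixture(scope="session")
def untrained_results(identity_corpus):
    """Randomly initialised model over the toy-grammar vocabulary; decoding
    contracts must hold regardless of training."""
    return make_untrained_results(identity_corpus[:200], seed=5)
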