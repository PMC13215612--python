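import numpy as np
import pytest

from pepflow import (
    AminoAcidVocabulary,
    ModelConfig,
    PepFlowModel,
    SimulationConfig,
    TrainingConfig,
    preprocess,
    simulate_dataset,
)
from pepflow.training import Trainer


@pytest.fixture(scope="session")
def vocab():
    return AminoAcidVocabulary.default()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest architecture exercising every component."""
    return ModelConfig(
        d_model=32,
        d_z=8,
        n_enc_layers=1,
        n_post_layers=1,
        n_dec_layers=1,
        n_heads=2,
        ffn_mult=2,
        n_flow_steps=3,
        n_flow_heads=2,
        n_cond_layers=1,
    )


@pytest.fixture()
def tiny_model(tiny_config, vocab):
    return PepFlowModel(tiny_config, vocab, np.random.default_rng(7))


@pytest.fixture(scope="session")
def noiseless_spectra():
    """A small clean b/y dataset (the generator's default conditions)."""
    cfg = SimulationConfig(n_peptides=32, seed=5)
    return [preprocess(sp) for sp in simulate_dataset(cfg)]


@pytest.fixture(scope="session")
def memorized():
    """A small model trained to memorize 10 noiseless spectra.

    Shared by the overfit smoke tests (argmax decoding, staged decoding,
    determinism); training it once keeps the suite fast.
    """
    vocab = AminoAcidVocabulary.default()
    config = ModelConfig(
        d_model=48,
        d_z=16,
        n_enc_layers=1,
        n_post_layers=1,
        n_dec_layers=1,
        n_heads=4,
        ffn_mult=2,
        n_flow_steps=2,
        n_flow_heads=2,
        n_cond_layers=1,
    )
    model = PepFlowModel(config, vocab, np.random.default_rng(1))
    spectra = [
        preprocess(sp)
        for sp in simulate_dataset(SimulationConfig(n_peptides=10, seed=21))
    ]
    trainer = Trainer(
        model,
        TrainingConfig(batch_size=10, lr=2e-3, seed=0),
        total_steps=500,
    )
    order_rng = np.random.default_rng(2)
    for _ in range(500):
        batch = [spectra[i] for i in order_rng.permutation(10)]
        trainer.train_step(batch)
    return model, spectra
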