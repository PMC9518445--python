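import numpy as np
import pytest

from capfusion.encoding import ModelConfig
from capfusion.fusion_model import TrainingHyperparams
from capfusion.synthetic_data import GeneratorParams, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 subjects, 2 minutes each, events visible on every channel."""
    return generate_cohort(GeneratorParams(n_subjects=4, duration_s=120.0, seed=7))


@pytest.fixture(scope="session")
def tiny_config():
    """A deliberately small fused architecture for fast training in tests."""
    return ModelConfig(
        channel_mask=(True, True, True),
        time_steps=2,
        n_recurrent_layers=1,
        recurrent_type="bidirectional",
        hidden_units=8,
        dropout=0.05,
        dense_size=0,
        dense_activation="tanh",
    )


@pytest.fixture(scope="session")
def tiny_hp():
    # batches here are smaller than batch_size, so epochs == Adam steps
    return TrainingHyperparams(max_training_epochs=15, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
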