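import numpy as np
import pytest

import somnostage as ss


@pytest.fixture(scope="session")
def default_specs():
    return ss.default_stage_specs()


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two subjects, one night of 12 epochs each, at the generation rate."""
    return ss.generate_dataset(2, 1, 12, fs_hz=100.0, seed=42)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down but structurally complete model configuration."""
    return ss.ModelConfig(
        input_len=30,
        input_channels=2,
        lstm_units=8,
        lstm_layers=2,
        conv_specs=((8, 3), (4, 3)),
        pool_size=2,
        fc_sizes=(16,),
        n_classes=5,
        dropout_conv=0.1,
        dropout_fc=0.2,
        input_scale_uv=100.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
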