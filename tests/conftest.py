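import numpy as np
import pytest
from hypothesis import settings

from cpcnn.cascade import CascadeConfig, train
from cpcnn.phantoms import PhantomSpec, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=10,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def micro_spec():
    """A miniature phantom spec for fast structural tests."""
    return PhantomSpec(base_resolution=(64, 32), seed=7)


@pytest.fixture(scope="session")
def micro_cases(micro_spec):
    return generate_dataset(micro_spec, 16)


@pytest.fixture(scope="session")
def micro_config():
    """A miniature cascade config matching micro_spec's resolution."""
    return CascadeConfig.tiny(base_size=(64, 32), epochs_primary=2,
                              epochs_cascade=1, batch_size=4, seed=11)


@pytest.fixture(scope="session")
def trained_micro_model(micro_cases, micro_config):
    """One briefly-trained micro cascade, shared across read-only tests."""
    return train(micro_cases, micro_config)


@pytest.fixture(scope="session")
def small_recovery():
    """A cascade trained well enough to discriminate (held-out AUC near 1)
    at reduced resolution, shared by tests that need a working model."""
    train_cases = generate_dataset(PhantomSpec(base_resolution=(96, 48), seed=51), 80)
    test_cases = generate_dataset(PhantomSpec(base_resolution=(96, 48), seed=52), 40)
    config = CascadeConfig.tiny(base_size=(96, 48), epochs_primary=3,
                                epochs_cascade=4, seed=5)
    model = train(train_cases, config)
    return model, test_cases


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
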