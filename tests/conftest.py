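import numpy as np
import pytest

from icbt_cea import ModelConfig, load_parameters, sample_parameter_set


@pytest.fixture(scope="session")
def params():
    """Default (base-case) parameter set."""
    return load_parameters()


@pytest.fixture(scope="session")
def config():
    """Reference structural configuration."""
    return ModelConfig()


@pytest.fixture(scope="session")
def perturbed_sets(params):
    """A deterministic collection of random valid parameter sets."""
    return [sample_parameter_set(params, seed) for seed in range(40)]
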