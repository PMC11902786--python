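import numpy as np
import pytest

from burnspec.synthetic import SyntheticConfig, generate

# reduced network used by desk-scale training tests; full-scale defaults
# (model_dim=16, state_dim=16, expand=2) are exercised by shape-only tests
DESK_MODEL = {"model_dim": 8, "state_dim": 8, "expand": 1}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dataset():
    """Small, fast, 40-band six-class dataset with mild noise."""
    return generate(SyntheticConfig(n_bands=40, samples_per_class=20, seed=7))


@pytest.fixture
def clean_tiny_dataset():
    """Noise-free 40-band dataset: every sample equals its class template."""
    return generate(SyntheticConfig(n_bands=40, samples_per_class=20,
                                    noise_sd=0.0, illum_scale_sd=0.0,
                                    interference_sd=0.0, seed=7))
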