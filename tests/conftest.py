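import numpy as np
import pytest

from ampatemp import ModelConfig


@pytest.fixture
def config() -> ModelConfig:
    """Reference parameter set (calyx-of-Held AMPAR fit)."""
    return ModelConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
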