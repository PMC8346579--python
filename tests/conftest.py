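import numpy as np
import pytest

from airwayseg import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom_config():
    """A 48^3 three-generation phantom: fast but morphologically complete."""
    return PhantomConfig(volume_shape=(48, 48, 48), n_generations=3, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config):
    return generate_phantom(small_phantom_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
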