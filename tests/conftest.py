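import numpy as np
import pytest

from renuseg.synth import SynthConfig, generate_image


@pytest.fixture(scope="session")
def small_tile():
    """One deterministic 256x256 tile with full ground truth."""
    return generate_image(SynthConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
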