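import numpy as np
import pytest

from ascunet import SynthSpec, generate_batch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_synth():
    """8 synthetic 64x64 samples: images (8,3,64,64) float32, masks (8,64,64)."""
    spec = SynthSpec(size=(64, 64), n_samples=8, seed=7)
    return generate_batch(spec)
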