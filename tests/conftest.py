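import numpy as np
import pytest

from socialvit.synth import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_synth():
    """40 uniform noise-free frames across 4 pseudo-videos (session-cached)."""
    return generate_dataset(40, seed=3, n_pseudo_videos=4)
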