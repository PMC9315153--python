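import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fiber_image():
    """One small native region reused by phantom/pipeline/io tests."""
    from polarscope.phantom import fiber_map_to_mueller, generate_fiber_map

    fmap = generate_fiber_map(96, 96, 10, seed=42)
    return fiber_map_to_mueller(fmap)
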