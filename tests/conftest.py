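import numpy as np
import pytest

from cardiopcct import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def phantom48():
    """Default-physiology phantom on the smallest grid that fits all structures."""
    return build_phantom(PhantomSpec(grid_shape=(48, 48, 48)))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
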