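import numpy as np
import pytest

from nichesim import default_community_spec, generate_community


@pytest.fixture(scope="session")
def small_community():
    """A seeded 60-site x 50-species community shared by read-only tests."""
    return generate_community(default_community_spec(60, 50, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
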