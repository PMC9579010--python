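import numpy as np
import pytest

from numerotune.stimgen import build_block_timeline, build_localizer_timeline


@pytest.fixture(scope="session")
def localizer_timeline():
    return build_localizer_timeline(seed=0)


@pytest.fixture(scope="session")
def block_timeline():
    return build_block_timeline(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
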