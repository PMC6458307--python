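import numpy as np
import pytest

from smlmpipe.geometry import Region


@pytest.fixture
def roi() -> Region:
    """The standard 3 x 3 um analysis window."""
    return Region(0.0, 0.0, 3000.0, 3000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
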