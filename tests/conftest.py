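import numpy as np
import pytest

from spdcm.model import ParamLayout, build_connectivity_mask


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def layout3():
    """3-node hub-and-spoke layout used throughout the fast tests."""
    return ParamLayout(build_connectivity_mask(("SubC", "A1", "V1"), 0))


@pytest.fixture
def layout5():
    return ParamLayout(
        build_connectivity_mask(("SubC", "vS1", "dS1", "A1", "V1"), 0)
    )
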