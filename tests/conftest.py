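import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cardinal_sample():
    """The four cardinal directions: perfectly cancelling mean vector."""
    from circmanova import to_radians

    return to_radians([0.0, 90.0, 180.0, 270.0], "degrees")
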