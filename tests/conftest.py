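import numpy as np
import pytest


@pytest.fixture(scope="session")
def example1_theta():
    """10,000 sign-test success probabilities: 100 at 0.8, 9,900 null."""
    return np.repeat([0.8, 0.5], [100, 9900])


@pytest.fixture(scope="session")
def tradeoff_delta():
    """100 two-sample-t effects: 95 null, 5 at a standardized difference of 2."""
    return np.repeat([0.0, 2.0], [95, 5])
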