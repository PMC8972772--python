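import numpy as np
import pytest

from condtau import LabeledSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sample(rng):
    """40 observations, 2 responses linked to Z, moderate dependence."""
    Z = rng.uniform(0.0, 1.0, 40)
    e1 = rng.normal(size=40)
    e2 = 0.6 * e1 + 0.8 * rng.normal(size=40)
    Y = np.column_stack([2.0 * Z + e1, -Z + e2])
    return LabeledSample(Y, Z)
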