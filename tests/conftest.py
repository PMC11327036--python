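import numpy as np
import pytest

from idar.synthetic import GeneratorSpec, gen_ar, gen_white


@pytest.fixture
def ar1_series():
    """Moderately correlated AR(1) series, fixed seed."""
    return gen_ar(GeneratorSpec("ar", (0.6,), 1.0, 1500, 1.0, 42))


@pytest.fixture
def white_series():
    return gen_white(800, 1.0, 42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
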