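import numpy as np
import pytest

import scrofit as sf


@pytest.fixture(scope="session")
def oscillator_scenario():
    """One 15%-noise oscillator dataset shared by read-only tests."""
    model = sf.get_model("oscillator")
    truth, data, real_var = sf.make_benchmark(
        model, noise=sf.NoiseSpec(percent=15.0), seed=123
    )
    return model, truth, data, real_var


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def box3():
    """A plain 3-dimensional box search space for optimizer unit tests."""
    return sf.ParameterSet(
        ["x", "y", "z"], np.zeros(3), -5.0 * np.ones(3), 5.0 * np.ones(3)
    )
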