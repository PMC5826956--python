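import numpy as np
import pytest

from lcagrowth.model_spec import Condition, build_true_model
from lcagrowth.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def high_sep_model():
    """Generating model at high separation, large smaller class."""
    return build_true_model(Condition(2000, 0.30, "high"))


@pytest.fixture(scope="session")
def high_sep_dataset(high_sep_model):
    return generate_dataset(high_sep_model, 2000, seed=42)


@pytest.fixture(scope="session")
def big_dataset(high_sep_model):
    """Large sample for moment-convergence checks."""
    return generate_dataset(high_sep_model, 200_000, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180222)
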