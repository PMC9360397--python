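import numpy as np
import pytest

from serumhb.synthetic import ForwardModelParams, generate_design, generate_samples


@pytest.fixture(scope="session")
def params():
    return ForwardModelParams()


@pytest.fixture(scope="session")
def full_design():
    """The 10-animal, 7-level crossed design."""
    return generate_design(10, seed=42)


@pytest.fixture(scope="session")
def sample_table(full_design):
    """A full synthetic 70-row sample table (seed 42)."""
    return generate_samples(full_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
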