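import numpy as np
import pytest

from vasrrp import (
    generate_dataset,
    implied_covariance,
    make_4l4i_spec,
)


@pytest.fixture(scope="session")
def spec_4l4i():
    return make_4l4i_spec()


@pytest.fixture(scope="session")
def sigma_4l4i(spec_4l4i):
    return implied_covariance(spec_4l4i)


@pytest.fixture(scope="session")
def big_dataset(spec_4l4i):
    """One large draw for law-of-large-numbers checks."""
    return generate_dataset(spec_4l4i, 50_000, seed=20240)


@pytest.fixture(scope="session")
def small_dataset(spec_4l4i):
    return generate_dataset(spec_4l4i, 500, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
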