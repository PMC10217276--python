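import numpy as np
import pytest

from visbrix.synthetic import SyntheticConfig, generate, make_fixture


@pytest.fixture(scope="session")
def clean_set():
    """Zero-corruption fixture: absorbance exactly linear in SSC."""
    return make_fixture("clean", seed=7)


@pytest.fixture(scope="session")
def noisy_set():
    return make_fixture("noisy", seed=7)


@pytest.fixture(scope="session")
def scattered_set():
    return make_fixture("scattered", seed=7)


@pytest.fixture(scope="session")
def cohort_set():
    """Default 100-sample study cohort, noise-free."""
    return generate(SyntheticConfig(n_samples=100, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
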