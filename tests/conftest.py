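import numpy as np
import pytest

from padem import base_case_config, expected_draw, run_psa


@pytest.fixture(scope="session")
def base_config():
    return base_case_config()


@pytest.fixture(scope="session")
def ev_draw(base_config):
    """Deterministic draw with every input at its analytic mean."""
    return expected_draw(base_config)


@pytest.fixture(scope="session")
def base_psa(base_config):
    """One shared 20,000-iteration base-case PSA run."""
    return run_psa(base_config, n_samples=20000, seed=20210817)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
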