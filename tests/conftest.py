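import numpy as np
import pytest

from serpinmr import generate_scenario, render_peaklists


@pytest.fixture(scope="session")
def scenario():
    """Default ground-truth scenario: 150 sites, 3 variants, local outliers."""
    return generate_scenario(n_sites=150, seed=11)


@pytest.fixture(scope="session")
def peaklists(scenario):
    return render_peaklists(scenario)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
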