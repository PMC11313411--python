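import numpy as np
import pytest

from poolhmm import preprocess as prep
from poolhmm import synthetic


@pytest.fixture(scope="session")
def default_data():
    """Default scenario with planted artifacts, simulated once per session."""
    sc = synthetic.default_scenario(seed=1)
    return synthetic.simulate_scenario(sc, with_artifacts=True)


@pytest.fixture(scope="session")
def default_preprocessed(default_data):
    sc = default_data.config
    return prep.preprocess(
        default_data.receivers,
        default_data.tags,
        default_data.detections,
        sc.calendar,
        sc.n_pools,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240806)
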