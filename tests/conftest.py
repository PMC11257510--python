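import numpy as np
import pytest

from threatdyn import (
    NeuralScenario,
    canonical_hrf,
    generate_timeline,
)


@pytest.fixture(scope="session")
def hrf():
    return canonical_hrf()


@pytest.fixture(scope="session")
def timeline():
    """Default MTC session used across tests."""
    return generate_timeline(seed=1)


@pytest.fixture(scope="session")
def small_timeline():
    """A 1-scan session for cheap design tests."""
    return generate_timeline(seed=2, n_scans=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mixed_scenario():
    """Sustained uncertain-threat plus phasic certain-threat dynamics."""
    return NeuralScenario(
        amplitudes={
            "uncertain_threat": {"sustained": 0.5},
            "certain_threat": {"phasic": 0.5},
        }
    )
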