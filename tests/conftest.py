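import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from halluxgrip.posture import fit_polynomial, load_reference_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_dataset():
    return load_reference_dataset()


@pytest.fixture(scope="session")
def quartic_model(reference_dataset):
    return fit_polynomial(reference_dataset, 4)


@pytest.fixture
def rng():
    return np.random.default_rng(20230602)
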