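import numpy as np
import pytest

from cdipatterns import IntegrationSettings, ModelParams
from cdipatterns.experiments import DEFAULT_DELTA


@pytest.fixture(scope="session")
def delta() -> float:
    """Grid spacing of the reference setup (length-10 domain, 32 points)."""
    return DEFAULT_DELTA


@pytest.fixture(scope="session")
def settings() -> IntegrationSettings:
    return IntegrationSettings(max_time=3e5)


@pytest.fixture
def reference_params(delta) -> ModelParams:
    """The Table-1 reference point: growth advantage 3.5, c1 = 2.0, D = 1e-3."""
    return ModelParams.from_c1(3.5, 2.0, D=1e-3, delta=delta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140227)
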