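import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ramlmodel.competing_mortality import MortalityParams
from ramlmodel.leukemogenesis import LeukemogenesisParams
from ramlmodel.radiobiology import RadiosensitivityParams


@pytest.fixture(scope="session")
def rp() -> RadiosensitivityParams:
    return RadiosensitivityParams()


@pytest.fixture(scope="session")
def lp() -> LeukemogenesisParams:
    return LeukemogenesisParams()


@pytest.fixture(scope="session")
def mp() -> MortalityParams:
    return MortalityParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220721)
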