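import logging

import numpy as np
import pytest
from hypothesis import settings

from catchcurve import GrowthParams

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

# over-asymptote drop warnings are expected noise in simulation-heavy tests
logging.getLogger("catchcurve.growth").setLevel(logging.ERROR)


@pytest.fixture
def loco_growth() -> GrowthParams:
    return GrowthParams(linf=150.0, k=0.433, t0=0.0)


@pytest.fixture
def limpet_growth() -> GrowthParams:
    return GrowthParams(linf=110.0, k=0.160, t0=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
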