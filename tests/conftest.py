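import numpy as np
import pytest

from fibrolyse.simulate import TraceModelParams
from fibrolyse.study import fixture_cohort_from_tables


@pytest.fixture(scope="session")
def base_params() -> TraceModelParams:
    """Default formation kinetics: 45 s lag, 0.01/s growth, 60 mm plateau."""
    return TraceModelParams(t0=45.0, k=0.01, mcf_true=60.0)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 64-subject cohort realizing the published tables."""
    return fixture_cohort_from_tables()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
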