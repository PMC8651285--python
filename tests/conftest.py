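import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import evcompare.sec as sm
from evcompare import Species, make_column
from evcompare.synthetic import ALBUMIN_RADIUS_NM, DEFAULT_EV_SIZE

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cl6b_10ml():
    return make_column(sm.SEPHAROSE_CL6B, 10.0)


@pytest.fixture(scope="session")
def ten_ml_columns():
    """Custom 10-ml columns keyed by resin short name."""
    return {
        "CL-2B": make_column(sm.SEPHAROSE_CL2B, 10.0),
        "CL-4B": make_column(sm.SEPHAROSE_CL4B, 10.0),
        "CL-6B": make_column(sm.SEPHAROSE_CL6B, 10.0),
    }


@pytest.fixture(scope="session")
def twenty_ml_columns():
    return {
        "CL-2B": make_column(sm.SEPHAROSE_CL2B, 20.0),
        "CL-4B": make_column(sm.SEPHAROSE_CL4B, 20.0),
        "CL-6B": make_column(sm.SEPHAROSE_CL6B, 20.0),
    }


@pytest.fixture(scope="session")
def ev_species():
    return Species("EV", DEFAULT_EV_SIZE, input_amount=1.0)


@pytest.fixture(scope="session")
def albumin_species():
    return Species("ALB", ALBUMIN_RADIUS_NM, input_amount=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
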