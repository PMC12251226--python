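import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")

from apdbench.datasets import load_study_tables
from apdbench.models import get_model


@pytest.fixture(scope="session")
def tables():
    return load_study_tables()


@pytest.fixture(scope="session")
def tp():
    return get_model("TP")


@pytest.fixture(scope="session")
def ord_model():
    return get_model("ORd")


@pytest.fixture(scope="session")
def gpb():
    return get_model("GPB")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
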