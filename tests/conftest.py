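import numpy as np
import pytest

from growthsense import make_fixture
from growthsense.datasets import (
    load_enose_summary,
    load_pc_scores,
    load_platecount_params,
)


@pytest.fixture(scope="session")
def enose_summary():
    return load_enose_summary()


@pytest.fixture(scope="session")
def pc_scores():
    """(scores frame indexed by time, variance percentages)."""
    return load_pc_scores()


@pytest.fixture(scope="session")
def platecount_params():
    return load_platecount_params()


@pytest.fixture(scope="session")
def study_grid():
    return np.arange(0.0, 169.0, 12.0)


@pytest.fixture(scope="session")
def fixture1():
    return make_fixture(seed=1)
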