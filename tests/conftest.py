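import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from umni.criteria import default_criteria, default_weights
from umni.scores import ScoreMatrix
from umni.synth import gen_rater_pair

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def criteria():
    return default_criteria()


@pytest.fixture(scope="session")
def weights():
    return default_weights()


@pytest.fixture(scope="session")
def rater_pair():
    """Seeded 40-disease expert/second-rater pair with realistic disagreement."""
    return gen_rater_pair(40, rates={1: 0.2045, 2: 0.0545}, seed=20260930)


def make_matrix(values, rater_id="test", criteria_names=None):
    """Small ScoreMatrix from a 2-D array; rows get synthetic MONDO ids."""
    arr = np.asarray(values, dtype=float)
    ids = [f"MONDO:{9100000 + i:07d}" for i in range(arr.shape[0])]
    cols = criteria_names or default_criteria().names[: arr.shape[1]]
    return ScoreMatrix(rater_id, pd.DataFrame(arr, index=ids, columns=cols))


@pytest.fixture
def matrix_factory():
    return make_matrix
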