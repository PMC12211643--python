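import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from smartmiss import table1_preset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def presets():
    return {s: table1_preset(s) for s in range(1, 6)}


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def balanced_table():
    """All 16 (O1, A1, O2, A2) cells once, Y = 0; a saturated orthogonal
    design useful for exact OLS checks."""
    rows = [
        dict(O1=o1, A1=a1, O2=o2, A2=a2, Y=0.0)
        for o1, a1, o2, a2 in itertools.product((-1.0, 1.0), repeat=4)
    ]
    return pd.DataFrame(rows)
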