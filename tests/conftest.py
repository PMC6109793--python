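import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def balanced_table():
    """4 genotypes x 2 environments, hand-pickable numbers."""
    rows = []
    values = {
        ("g1", "E1"): 10.0, ("g1", "E2"): 12.0,
        ("g2", "E1"): 8.0, ("g2", "E2"): 11.0,
        ("g3", "E1"): 13.0, ("g3", "E2"): 15.0,
        ("g4", "E1"): 9.0, ("g4", "E2"): 10.0,
    }
    for (gid, env), val in values.items():
        rows.append({"genotype_id": gid, "environment_id": env,
                     "trait_name": "BY", "value": val})
    return pd.DataFrame(rows)
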