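import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def single_pub_frame() -> pd.DataFrame:
    """One publication, four dose levels — the smallest mixed-model case."""
    return pd.DataFrame(
        {
            "publication_id": "pub0001",
            "n_rate_kg_ha": [0.0, 100.0, 200.0, 300.0],
            "n2o_kg_n_ha_yr": [1.1, 2.0, 2.5, 4.0],
        }
    )


@pytest.fixture
def multi_pub_frame() -> pd.DataFrame:
    """Five publications with ragged group sizes and noisy emissions."""
    rng = np.random.default_rng(12345)
    rows = []
    for i in range(5):
        for _ in range(int(rng.integers(2, 6))):
            rows.append(
                {
                    "publication_id": f"p{i}",
                    "n_rate_kg_ha": float(rng.uniform(0, 400)),
                    "n2o_kg_n_ha_yr": float(rng.normal(2.0, 2.0)),
                }
            )
    return pd.DataFrame(rows)
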