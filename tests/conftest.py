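import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dkdrisk.priors import load_registry
from dkdrisk.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-condition synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=6000, seed=11))


@pytest.fixture()
def tiny_cohort_csv(tmp_path):
    """Three hand-written patient rows on disk."""
    path = tmp_path / "tiny.csv"
    pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "index_date": ["2019-01", "2019-06", "2020-02"],
            "age": [60.0, 55.0, 70.0],
            "sex": ["female", "male", "female"],
            "egfr": [95.0, 62.0, 48.0],
            "acr": [12.0, 40.0, np.nan],
            "hba1c": [7.5, np.nan, 9.0],
            "followup_months": [40, 12, 36],
            "event": [False, True, False],
            "censor_reason": ["administrative", "none", "administrative"],
        }
    ).to_csv(path, index=False)
    return path
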