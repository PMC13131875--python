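import numpy as np
import pytest

from epicohort.syncohort import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def signal_config():
    """Cohort config with genetic, environmental, and confounder signal."""
    return CohortConfig(
        n_participants=2500,
        n_variants=80,
        prevalence_target=0.33,
        wgs_fraction=0.5,
        variant_effects={f"v{j:05d}": w for j, w in [(0, 0.5), (1, -0.4), (2, 0.3)]},
        env_effects={"smoker": 0.8, "sleep_hours": -0.15, "exercise_level": -0.2},
        confounder_effects={"age": 0.4, "sex": 0.2, "bmi": 0.5},
        item_missing_rate=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def signal_cohort(signal_config):
    return generate_cohort(signal_config)
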