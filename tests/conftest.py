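import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pcgclust as pc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def taxonomy():
    return pc.default_taxonomy()


@pytest.fixture(scope="session")
def small_default_cohort():
    """Stochastic draw from the default archetype mixture, desk scale."""
    spec = pc.default_cohort_spec(seed=11)
    spec.n_patients = 600
    return pc.generate_cohort(spec, mode="stochastic")


@pytest.fixture(scope="session")
def planted_cohort():
    """Planted four-archetype cohort for recovery-style checks."""
    spec = pc.planted_archetype_spec(n_patients=400, separation=1.0, seed=7)
    return pc.generate_cohort(spec, mode="stochastic")


def make_cohort_from_flags(flags, taxonomy):
    """Minimal cohort table around an explicit (n, 34) flag matrix."""
    flags = np.asarray(flags)
    n = flags.shape[0]
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "true_archetype": ["fixture"] * n,
            "age": np.full(n, 60.0),
            "sex": ["F"] * n,
            "deductible": np.full(n, 500.0),
            "gatekeeper": np.zeros(n, dtype=int),
            "ambulatory_cost": np.full(n, 100.0),
            "inpatient_cost": np.full(n, 50.0),
            "medication_cost": np.full(n, 25.0),
            "hospital_days": np.zeros(n, dtype=int),
            "hospitalizations": np.zeros(n, dtype=int),
            "consultations_total": np.full(n, 3, dtype=int),
            "consultations_generalist": np.full(n, 2, dtype=int),
        }
    )
    for j, name in enumerate(taxonomy.names):
        df[f"pcg_{name}"] = flags[:, j]
    df["total_cost"] = df.ambulatory_cost + df.inpatient_cost + df.medication_cost
    return df


@pytest.fixture
def flags_cohort_factory(taxonomy):
    def factory(flags):
        return make_cohort_from_flags(flags, taxonomy)

    return factory
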