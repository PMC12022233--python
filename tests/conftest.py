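import numpy as np
import pytest

from myodx.cohort import CohortTable, SampleRecord
from myodx.harmonize import harmonize_cohort
from myodx.synthetic import default_specs, generate_cohort
from myodx.taxonomy import default_taxonomy


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete synthetic cohort (~60 samples)."""
    spec = default_specs(n_patients=8)
    cohort, truth = generate_cohort(spec, seed=5)
    return cohort, truth


@pytest.fixture(scope="session")
def harmonized_small(small_cohort):
    cohort, _ = small_cohort
    return harmonize_cohort(cohort)


@pytest.fixture
def ff_record():
    """A unilateral fat-fraction record with a few muscles."""
    return SampleRecord(
        sample_id="s1", patient_id="p1", source_id="src", disease="d",
        age=40.0, sex="M", side_mode="unilateral", scale="FF",
        scores={"peroneus_brevis": 20.0, "peroneus_longus": 40.0,
                "soleus": 70.0},
    )


@pytest.fixture
def bilateral_record():
    """A bilateral Mercuri 0-4 record (scores in rank space)."""
    return SampleRecord(
        sample_id="s2", patient_id="p2", source_id="src", disease="d",
        age=30.0, sex="F", side_mode="bilateral", scale="0-4",
        scores={"peroneus_brevis": (0.0, 4.0), "peroneus_longus": (2.0, 2.0),
                "soleus": (1.0, 3.0)},
    )


@pytest.fixture
def taxonomy():
    return default_taxonomy()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
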