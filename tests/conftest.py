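import numpy as np
import pytest

from blubbercort.data_model import SpecimenRecord
from blubbercort.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default 23 stranded + 40 bycaught synthetic cohort."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(i=0, **overrides):
    """Minimal valid specimen with overridable fields."""
    base = dict(
        specimen_id=f"T-{i:03d}",
        fatality_type="bycatch",
        cortisol=4.0,
        total_length=180.0,
        sex="female",
        maturity="mature",
        pregnancy="no",
        lactation="no",
        adrenal_mass=2.5,
        collection_month=10,
        storage_days=100.0,
    )
    base.update(overrides)
    return SpecimenRecord(**base)
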