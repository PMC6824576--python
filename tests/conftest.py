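import numpy as np
import pytest
from hypothesis import settings

from immunonoise import CohortTable, default_table2_config, generate_cohort

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Hand-written 3-patient, 2-parameter cohort."""
    return CohortTable(
        patient_ids=["a", "b", "c"],
        parameter_names=["IL1", "CD4_pct"],
        values=np.array([[1.0, 30.0], [2.0, 40.0], [3.5, -0.17]]),
        group_labels=["EOP", "EOP", "LOP"],
    )


@pytest.fixture(scope="session")
def default_cohort() -> "CohortTable":
    """One seeded draw of the packaged study-sized configuration."""
    return generate_cohort(default_table2_config(seed=0))


@pytest.fixture(scope="session")
def collinear_cohort():
    return generate_cohort(default_table2_config(seed=0, structure="collinear"))
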