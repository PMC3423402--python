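import numpy as np
import pytest

from connmod import cohort as cohort_mod
from connmod import connectivity as conn_mod


@pytest.fixture(scope="session")
def small_config():
    """A 10-subject, 20-region cohort small enough for fast end-to-end runs."""
    return cohort_mod.CohortConfig(
        n_control=5,
        n_patient=5,
        n_regions=20,
        n_timepoints=120,
        k_modules=3,
        n_affected_down=4,
        n_affected_up=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return cohort_mod.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_penalized(small_cohort):
    """Penalized matrices and distance models for the small cohort."""
    out = [
        conn_mod.penalize(conn_mod.compute_correlation(s), small_cohort.parcellation)
        for s in small_cohort.subjects
    ]
    pens, models = zip(*out)
    return list(pens), list(models)


@pytest.fixture(scope="session")
def default_parcellation():
    return cohort_mod.make_parcellation(95, seed=0)
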