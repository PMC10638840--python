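import numpy as np
import pytest

from mmdti import (
    CohortConfig,
    ProfileConfig,
    RateMatrixModel,
    generate_cohort,
    generate_tract_profiles,
)


@pytest.fixture(scope="session")
def toy_rate_model():
    """The 3-rate toy intensity model: NC->aMCI 0.2, aMCI->NC 0.1, aMCI->AD 0.3."""
    return RateMatrixModel(
        baseline_rates={("NC", "aMCI"): 0.2, ("aMCI", "NC"): 0.1, ("aMCI", "AD"): 0.3})


@pytest.fixture(scope="session")
def toy_Q(toy_rate_model):
    return toy_rate_model.rate_matrix()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort (120 subjects, Table-1-like structure)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    cfg = ProfileConfig(seed=12)
    return generate_tract_profiles(
        cfg, small_cohort.groups,
        age={s.subject_id: float(s.covariates[0]) for s in small_cohort.subjects},
        sex={s.subject_id: int(s.covariates[1]) for s in small_cohort.subjects})


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
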