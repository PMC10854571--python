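import numpy as np
import pandas as pd
import pytest

from zbln_aft.cohort import CohortTable, CovariateSpec, lung_cancer_covariates
from zbln_aft.simulate import default_scenario, generate_cohort


@pytest.fixture(scope="session")
def paper_specs():
    return lung_cancer_covariates()


@pytest.fixture
def toy_specs():
    return (
        CovariateSpec("age", "continuous"),
        CovariateSpec("race", "categorical",
                      ("American Indian", "Asian", "Black", "White"),
                      "American Indian"),
        CovariateSpec("gender", "categorical", ("Male", "Female"), "Male"),
    )


@pytest.fixture
def toy_cohort(toy_specs):
    df = pd.DataFrame(
        {
            "time": [5.0, 12.5, 36.0],
            "event": [1, 1, 0],
            "age": [60.0, 71.0, 55.0],
            "race": ["White", "Asian", "American Indian"],
            "gender": ["Male", "Female", "Male"],
        }
    )
    return CohortTable(df, toy_specs, horizon=36)


@pytest.fixture(scope="session")
def small_synthetic_cohort():
    """One modest simulated study cohort shared by read-only tests."""
    return generate_cohort(default_scenario(36, n=2000, seed=11))


def fitting_covariates(cohort):
    """Covariates with non-constant design columns (drops degenerate TISP)."""
    from zbln_aft.cohort import encode_design

    X, names = encode_design(cohort)
    keep = []
    for s in cohort.specs:
        cols = [j for j, c in enumerate(names) if c.split(":")[0] == s.name]
        if all(np.ptp(X[:, j]) > 0 for j in cols):
            keep.append(s.name)
    return tuple(keep)
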