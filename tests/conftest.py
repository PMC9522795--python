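import numpy as np
import pandas as pd
import pytest

from lungage import generate_healthy


@pytest.fixture(scope="session")
def healthy_cohort() -> pd.DataFrame:
    """Moderate healthy cohort shared by fitting tests."""
    return generate_healthy("healthy_modelling", n=1200, seed=20220929)


@pytest.fixture(scope="session")
def male_cohort(healthy_cohort) -> pd.DataFrame:
    return healthy_cohort.loc[healthy_cohort["sex"] == "male"].reset_index(drop=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_linear_records(n=300, seed=0, sex="male"):
    """Records whose age is an exact linear function of the predictors."""
    r = np.random.default_rng(seed)
    height = r.uniform(150, 190, n)
    fev1 = r.uniform(1.5, 5.5, n)
    fef50 = r.uniform(1.0, 8.0, n)
    fef75 = r.uniform(0.3, 4.0, n)
    age = 10.0 + 0.2 * height - 6.0 * fev1 + 1.5 * fef50 - 4.0 * fef75
    fvc = fev1 / 0.8
    return pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(n)],
            "sex": sex,
            "age": age,
            "height": height,
            "fev1": fev1,
            "fvc": fvc,
            "fev1_fvc": fev1 / fvc,
            "mmef": fef50 * 0.8,
            "fef50": fef50,
            "fef75": fef75,
        }
    )
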