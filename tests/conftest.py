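import numpy as np
import pandas as pd
import pytest

from phenodelta.phenoage import six_marker_spec
from phenodelta.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def spec6():
    return six_marker_spec()


@pytest.fixture
def healthy_panel():
    """Fixed mid-life panel in scoring units."""
    return {"mcv": 90.0, "wbc": 6.2, "albumin": 45.0, "creatinine": 70.0,
            "glucose": 5.3, "chron_age": 50.0}


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mixed-sex synthetic cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n=6000, seed=20240915))


@pytest.fixture(scope="session")
def male_config():
    """Single-sex generating conditions used by the recovery experiments."""
    return GeneratorConfig(n=25_000, sex_fraction_male=1.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)


@pytest.fixture
def random_regression():
    """Factory for small random regression instances."""
    def make(seed, n=120, p=8, sparsity=0.3, beta_scale=0.5):
        r = np.random.default_rng(seed)
        X = r.standard_normal((n, p))
        beta = np.where(r.random(p) < sparsity, r.normal(0, beta_scale, p), 0.0)
        y = X @ beta + r.standard_normal(n)
        df = pd.DataFrame(X, columns=[f"c{j:02d}" for j in range(p)])
        df["y"] = y
        df["forced0"] = r.standard_normal(n)
        return df, [f"c{j:02d}" for j in range(p)], beta
    return make
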