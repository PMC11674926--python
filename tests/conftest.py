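import numpy as np
import pytest

from mgfs import (
    ReferenceCohort,
    SyntheticSpec,
    fit_normative_model,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def reference_cohort() -> ReferenceCohort:
    """Synthetic reference cohort with the published component structure."""
    return simulate_cohort(SyntheticSpec(n=2744, seed=0))


@pytest.fixture(scope="session")
def reference_model(reference_cohort):
    return fit_normative_model(reference_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_cohort(rng: np.random.Generator, n: int = 50, p: int = 5) -> ReferenceCohort:
    """Small unstructured cohort on p generic variables for oracle checks."""
    import pandas as pd

    names = tuple(f"v{j}" for j in range(p))
    x = rng.normal(size=(n, p)) @ rng.normal(size=(p, p)) + rng.normal(size=p)
    data = pd.DataFrame(x, columns=list(names))
    data.insert(0, "subject_id", [f"R{i}" for i in range(n)])
    return ReferenceCohort(data, names)
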