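import numpy as np
import pytest

from momcrad import CohortSpec, generate_cohort, generate_phantom
from momcrad.tables import FeatureTable


@pytest.fixture(scope="session")
def phantom():
    """Default sphere-with-lobes PET/CT phantom at 1 mm spacing."""
    return generate_phantom(seed=7)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(noise_sd=0.0, ct_noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def cohort():
    """Default study-sized cohort: 328 patients, 21% positive, 262/66 split."""
    return generate_cohort(CohortSpec(seed=0))


@pytest.fixture()
def toy_table():
    """Small separable two-class table for classifier-level tests."""
    rng = np.random.default_rng(5)
    n = 60
    y = np.array([0] * 40 + [1] * 20)
    rng.shuffle(y)
    X = rng.normal(0, 1, (n, 10))
    X[:, 2] += 2.0 * y
    X[:, 7] += 1.2 * y
    return FeatureTable(
        [f"p{i}" for i in range(n)], [f"f{j}" for j in range(10)], X, y
    )
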