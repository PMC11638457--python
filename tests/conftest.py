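import numpy as np
import pytest

from cirrdx import phantom


@pytest.fixture(scope="session")
def small_params():
    return phantom.PhantomParams(n_cases=12, prevalence=0.5, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return phantom.generate_cohort(small_params)


@pytest.fixture(scope="session")
def scored_fixture():
    """n=60 paired scores/labels for comparison tests."""
    rng = np.random.default_rng(7)
    labels = (rng.random(60) < 0.5).astype(int)
    a = labels * 0.8 + rng.normal(0, 0.6, 60)
    b = labels * 0.5 + rng.normal(0, 0.7, 60)
    return a, b, labels
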