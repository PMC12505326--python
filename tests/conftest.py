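import numpy as np
import pytest

from htefuse import Cohort, ScenarioSpec, generate_case


@pytest.fixture(scope="session")
def case2_cohort():
    """One moderate Case-2 fused cohort, shared across tests."""
    return generate_case(ScenarioSpec(case=2, n1=400, n0=800, seed=7))


@pytest.fixture(scope="session")
def case1_cohort():
    return generate_case(ScenarioSpec(case=1, n1=400, n0=800, seed=11))


@pytest.fixture()
def tiny_cohort():
    """Small deterministic fused cohort for contract checks."""
    rng = np.random.default_rng(3)
    n = 60
    x = rng.normal(0, 1, (n, 2))
    y = rng.exponential(2.0, n)
    delta = rng.binomial(1, 0.7, n)
    a = rng.binomial(1, 0.5, n)
    s = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
    return Cohort.from_arrays(y, delta, x, a, s, L=3.0)
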