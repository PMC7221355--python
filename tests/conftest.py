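import numpy as np
import pytest

import topoconnect as tc


def random_connectivity(n: int, rng: np.random.Generator) -> tc.ConnectivityMatrix:
    """A random valid correlation matrix via a Gram construction."""
    x = rng.standard_normal((n + 5, n))
    r = np.corrcoef(x, rowvar=False)
    return tc.ConnectivityMatrix(None, np.clip(r, -1, 1))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-group cohort with a moderate implanted effect."""
    spec = tc.CohortSpec(
        n_control=30,
        n_case=30,
        n_nodes=40,
        k=4,
        t_samples=100,
        effect_within=0.05,
        seed=42,
    )
    return tc.simulate_cohort(spec)


@pytest.fixture(scope="session")
def community_subject():
    """One control-like community-structured connectome at study scale."""
    spec = tc.CohortSpec(n_control=2, n_case=2, seed=7)
    cms, _, _ = tc.simulate_cohort(spec)
    return cms[0]
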