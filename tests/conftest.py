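import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mlogitdiag as m

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    return m.ModelSpec(terms=["sex", "twin"])


@pytest.fixture(scope="session")
def small_data(small_spec):
    """Six clusters, two strata, known zero-slope truth."""
    cfg = m.SyntheticConfig(
        n_clusters=6, cluster_size_range=(10, 16), model=small_spec, seed=11
    )
    data, truth = m.generate(cfg)
    return data, truth


@pytest.fixture(scope="session")
def small_fit(small_data, small_spec):
    data, _ = small_data
    return data, m.fit(data, small_spec)


@pytest.fixture(scope="session")
def medium_fit():
    """A richer fit (40 clusters, four covariates) for diagnostics tests."""
    spec = m.ModelSpec(terms=["birth_order", "twin", "caesarean", "sex"])
    cfg = m.SyntheticConfig(
        n_clusters=40, cluster_size_range=(12, 20), model=spec, seed=21
    )
    data, _ = m.generate(cfg)
    return data, spec, m.fit(data, spec)


def draw_multinomial_rows(rng, P):
    """Row-wise categorical draws from a probability matrix."""
    u = rng.random(P.shape[0])
    return (u[:, None] > np.cumsum(P, axis=1)).sum(axis=1)
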