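import numpy as np
import pytest

from dimix import StructuredMixture, GaussianComponent, four_component_example


@pytest.fixture(scope="session")
def benchmark_spec():
    return four_component_example()


@pytest.fixture(scope="session")
def benchmark_mixture(benchmark_spec):
    return benchmark_spec.to_mixture()


def random_mixture(seed: int, p: int = 1, n_components: int = 3) -> StructuredMixture:
    """Small random SPD mixture for property tests; deterministic in seed."""
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(n_components, 2.0))
    comps = []
    for k in range(n_components):
        mean = rng.normal(0, 3, size=p)
        a = rng.normal(0, 1, size=(p, p))
        cov = a @ a.T + (0.3 + rng.random()) * np.eye(p)
        comps.append(GaussianComponent(mean, cov, w[k]))
    return StructuredMixture(comps)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
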