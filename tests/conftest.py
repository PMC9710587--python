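import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scenario():
    """A small planted scenario shared by unit tests (fast to analyze)."""
    from cmapmeta.synthdata import generate_scenario

    return generate_scenario(
        n_genes=300, n_drugs=12, experiments_per_drug=20, n_active=3,
        strength=0.6, n_contrasts=2, seed=11,
    )


@pytest.fixture(scope="session")
def small_result(small_scenario):
    from cmapmeta import ConnectivityMapper

    query, ref, ann, truth = small_scenario
    mapper = ConnectivityMapper(
        min_experiments=20, permutations=500, random_state=11
    )
    return mapper.fit(ref, ann).analyze(query), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
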