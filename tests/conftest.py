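import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def taxa5():
    from sludge_archaea.synthetic import make_reference_taxa

    return make_reference_taxa(5, seed=7)


@pytest.fixture
def scenario(taxa5):
    from sludge_archaea.synthetic import CommunityScenario, skewed_weights

    return CommunityScenario(
        taxa=taxa5,
        abundance_weights=skewed_weights(5),
        drift=5,
        noise_sd=0.0,
        n_replicates=3,
        seed=11,
        spurious_rate=2.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
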