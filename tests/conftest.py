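import numpy as np
import pytest

from rohdice import plant_clusters


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def random_binary_panel(rng, M, N, density=0.5):
    """Random {0,1} panel; low density raises the match rate."""
    panel = (rng.random((M, N)) < density).astype(np.uint8)
    return panel


@pytest.fixture(scope="session")
def planted_fixture():
    """200 individuals, 1500 sites, one planted 150-site/120-member cluster."""
    panel, truth = plant_clusters(
        M=200, N=1500, cluster_specs=[(600, 750, 120, 0.0)], seed=42
    )
    return panel, truth
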