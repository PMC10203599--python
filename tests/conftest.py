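import numpy as np
import pytest

from lmdti.hetnet import DTISubnetwork
from lmdti.synthgen import PlantedConfig, generate_planted_hetnet, generate_toy_fixture


@pytest.fixture
def toy_subnetwork() -> DTISubnetwork:
    """3 drugs, 1 target: Sd(d1,d2)=0.5, Sd(d2,d3)=0.4, edges d1-t1, d3-t1."""
    return generate_toy_fixture()


def random_subnetwork(rng: np.random.Generator, n: int, m: int, density: float = 0.3) -> DTISubnetwork:
    """Random valid drug-target subnetwork with Uniform(0,1) similarities."""
    sd = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.5), 1)
    sd = sd + sd.T
    st = np.triu(rng.random((m, m)) * (rng.random((m, m)) < 0.5), 1)
    st = st + st.T
    a = (rng.random((n, m)) < density).astype(float)
    return DTISubnetwork(
        [f"d{i}" for i in range(n)], [f"t{j}" for j in range(m)], sd, st, a
    )


@pytest.fixture(scope="session")
def planted_default():
    """The default planted heterogeneous network (shared across tests)."""
    return generate_planted_hetnet(PlantedConfig())


@pytest.fixture(scope="session")
def planted_small():
    """A small planted network for fast end-to-end smoke tests."""
    return generate_planted_hetnet(
        PlantedConfig(n_drugs=24, n_targets=20, n_lncrna=8, n_mirna=8, n_clusters=2,
                      p_within=0.4, p_between=0.05, ncrna_density=0.1, seed=7)
    )
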