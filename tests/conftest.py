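import numpy as np
import pytest

import districtprev as dp
from districtprev import geo


@pytest.fixture(scope="session")
def lattice_3x3():
    return dp.generate_district_lattice(3, 3, 1.0)


@pytest.fixture(scope="session")
def small_survey():
    """Compact calibrated scenario used by several modules' tests."""
    cfg = dp.ScenarioConfig(
        n_districts_rows=4,
        n_districts_cols=5,
        cell_size_km=30.0,
        n_clusters=60,
        women_per_cluster_mean=20,
        seed=123,
    )
    dmap = dp.generate_district_lattice(4, 5, 30.0)
    adj = geo.build_adjacency(dmap)
    ds = dp.generate_survey(cfg, dmap, adj)
    return cfg, dmap, adj, ds


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
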