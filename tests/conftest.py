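import numpy as np
import pytest

import geotriad as gt


@pytest.fixture(scope="session")
def small_panel():
    """7x7 rook lattice, 8 years, 2 covariates; moderate noise."""
    cfg = gt.SimulationConfig(
        grid_rows=7,
        grid_cols=7,
        n_years=8,
        n_covariates=2,
        region_blocks=2,
        sd_mu=(0.5, 0.5),
        sd_gamma=(0.3, 0.3),
        beta=(1.0, -0.5),
        sd_eps=0.2,
        seed=5,
    )
    return gt.simulate_panel(cfg)


@pytest.fixture
def path3_weights():
    """Path graph 0-1-2."""
    return gt.SpatialWeights(3, [{1}, {0, 2}, {1}])


def random_symmetric_weights(n: int, p: float, rng: np.random.Generator) -> gt.SpatialWeights:
    """Erdos-Renyi symmetric binary weights (may be disconnected)."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    adj = adj | adj.T
    return gt.SpatialWeights(n, [set(np.nonzero(adj[i])[0].tolist()) for i in range(n)])
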