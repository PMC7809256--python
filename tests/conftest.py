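import numpy as np
import pytest

from bloomflux.metrics import derive_series
from bloomflux.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_series():
    """The reference single-pixel dataset: 50 years, seed 42, defaults."""
    cfg = SimConfig(seed=42, n_years=50, n_lat=1, n_lon=1)
    bundle = simulate_dataset(cfg)
    schl = bundle.schl.values[:, 0, 0]
    nhf = bundle.nhf.values[:, 0, 0]
    ws = bundle.ws.values[:, 0, 0]
    derived = derive_series(schl, nhf, ws, bundle.axis)
    return {"config": cfg, "bundle": bundle, "axis": bundle.axis,
            "schl": schl, "nhf": nhf, "ws": ws, "derived": derived}


@pytest.fixture(scope="session")
def default_grid():
    """The reference gridded dataset: 50 years, 8x8 pixels, seed 42."""
    cfg = SimConfig(seed=42, n_years=50, n_lat=8, n_lon=8)
    return {"config": cfg, "bundle": simulate_dataset(cfg)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
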