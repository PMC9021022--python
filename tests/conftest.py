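import numpy as np
import pytest

import paleohabitat as ph


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid():
    """6x8 all-land grid over a small African-like domain."""
    return ph.GridSpec.regular(10, 34, -9, 9, 3)


@pytest.fixture(scope="session")
def small_fields(small_grid):
    """200-slice four-variable trajectory with default forcing/noise."""
    spec = ph.default_climate_spec(n_time=200, seed=7)
    return ph.gen_climate_fields(small_grid, spec)


@pytest.fixture()
def quiet_spec():
    """Noise-free, forcing-free spec: every cell constant at its mean map."""
    spec = ph.default_climate_spec(n_time=50, seed=3)
    for vs in spec.variables.values():
        vs.noise_sd = 0.0
        vs.orbital = []
    return spec


def make_record(
    site="site_a", layer="L1", lon=20.0, lat=0.0, age=100.0, dt=5.0,
    species=("sapiens",), method="14C", region="",
):
    return ph.FossilRecord(
        site_name=site, layer_id=layer, lon=lon, lat=lat, age_ka=age,
        age_uncertainty_ka=dt, attributions=tuple(species),
        dating_method=method, region=region,
    )
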