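import logging

import numpy as np
import pytest

from firecast import standard_scenario
from firecast.io import month_index
from firecast.synth import SynthConfig, gen_emission_field, gen_oci_set

logging.getLogger("firecast").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_scenario():
    """A 4x4 synthetic world with short windows, shared across tests."""
    return standard_scenario(seed=42, n_lat=4, n_lon=4, dev_years=8, pred_years=2)


@pytest.fixture(scope="session")
def tiny_field():
    """A 6x6 field with one coupled block and one quiet corner."""
    ocis = gen_oci_set(3, 12 * 12 + 12, ar1_phi=0.8, innovation_sd=0.6,
                       seed=3, start_year=1996)
    cfg = SynthConfig(n_lat=6, n_lon=6, n_years=12, start_year=1997,
                      base_emission_map=1.2, noise_sd=0.25, seed=3)
    field, truth = gen_emission_field(cfg, ocis)
    return field, truth, ocis, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def monthly_index():
    return month_index(2000, 120)
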