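import numpy as np
import pytest

from svybkmr import (PopulationConfig, SamplingDesign, draw_sample,
                     generate_population, h_spec_for)


@pytest.fixture(scope="session")
def small_population():
    """2000 units, 20 PSUs, 4 strata — cheap but structurally faithful."""
    cfg = PopulationConfig(n_pop=2000, m=3, rho=0.0, icc=0.15,
                           n_psu=20, n_strata=4, seed=11)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def small_sample(small_population):
    design = SamplingDesign(n_total=120, k_h=3, regime="pps", seed=12)
    return draw_sample(small_population, design)


@pytest.fixture(scope="session")
def standard_population():
    """Full-size population under the default survey geometry."""
    cfg = PopulationConfig(n_pop=20_000, m=3, rho=0.0, icc=0.0, seed=21)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def h3():
    return h_spec_for(3)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
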