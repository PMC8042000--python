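import pytest

from leafopt import GeneratorConfig, generate, make_fixture
from leafopt.theory import EnvConditions


@pytest.fixture(scope="session")
def median_env():
    """The dataset's median climate: PPFD 400, Tg 25 degC, D 0.6 kPa, sea level."""
    return EnvConditions.from_climate(tg_c=25.0, d_kpa=0.60, ppfd=400.0,
                                      elevation_m=0.0)


@pytest.fixture(scope="session")
def default_sim():
    """One synthetic dataset under the default study conditions."""
    return generate(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def default_records(default_sim):
    """Species-at-site records joined to generating site climate."""
    return default_sim.records_with_climate()


@pytest.fixture(scope="session")
def minfunc_demo():
    """40 records generated exactly from two known limbs (sharp minimum)."""
    return make_fixture("minfunc_demo")
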