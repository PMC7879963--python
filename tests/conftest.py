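import pytest

from cvdsim.sensitivity import one_way
from cvdsim.toynation import FixtureConfig, make_surveillance_panel, make_toy_nation


@pytest.fixture(scope="session")
def nation():
    return make_toy_nation()


@pytest.fixture(scope="session")
def base_traj(nation):
    return nation.base_trajectory()


@pytest.fixture(scope="session")
def panel(nation, base_traj):
    return make_surveillance_panel(nation.config, base_traj)


@pytest.fixture(scope="session")
def noise_free_panel(nation, base_traj):
    cfg = FixtureConfig(noise=0.0, seed=nation.config.seed)
    return make_surveillance_panel(cfg, base_traj)


@pytest.fixture(scope="session")
def sweep_records(nation):
    runner = nation.deaths_averted_runner()
    return one_way(runner, nation.params, nation.bounds, outcome="deaths_averted")
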