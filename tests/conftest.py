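import numpy as np
import pytest

from ringkmc import (
    InhibitionScheme,
    RateTable,
    SimulationConfig,
    build_network,
    run,
)


@pytest.fixture(scope="session")
def default_rates():
    return RateTable()


@pytest.fixture(scope="session")
def schemes():
    return {
        "scheme1": InhibitionScheme.scheme1(),
        "scheme2": InhibitionScheme.scheme2(),
        "scheme3": InhibitionScheme.scheme3(),
        "none": InhibitionScheme.none(),
    }


@pytest.fixture(scope="session")
def network_1236(default_rates):
    return build_network("1236", default_rates, InhibitionScheme.scheme2())


@pytest.fixture(scope="session")
def pure_w_network(default_rates):
    return build_network("1236", default_rates, InhibitionScheme.none())


@pytest.fixture(scope="session")
def pure_w_trace(pure_w_network):
    """One default pure wild-type run, shared across tests."""
    cfg = SimulationConfig(n_Wt=1000, n_Mut=0, n_steps=100_000, seed=7,
                           scheme=InhibitionScheme.none())
    return run(cfg, network=pure_w_network)


# The printed per-configuration activity table: config_id -> (n_fast, n_basal)
# under full-ring, both-neighbour and oriented-neighbour inhibition.
ACTIVITY_TABLE = {
    1: ((6, 0), (6, 0), (6, 0)),
    2: ((0, 5), (3, 2), (4, 1)),
    3: ((0, 4), (2, 2), (3, 1)),
    4: ((0, 4), (1, 3), (2, 2)),
    5: ((0, 4), (0, 4), (2, 2)),
    6: ((0, 3), (1, 2), (2, 1)),
    7: ((0, 3), (0, 3), (1, 2)),
    8: ((0, 3), (0, 3), (1, 2)),
    9: ((0, 3), (0, 3), (0, 3)),
    10: ((0, 2), (0, 2), (1, 1)),
    11: ((0, 2), (0, 2), (0, 2)),
    12: ((0, 2), (0, 2), (0, 2)),
    13: ((0, 1), (0, 1), (0, 1)),
    14: ((0, 0), (0, 0), (0, 0)),
}
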