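"""Shared fixtures.

Heavy stochastic runs (the 5000-rep perturbation screen and the two
population simulations) are session-scoped so the acceptance checks and
unit tests share one computation each.
"""

import pytest

from yeastbkmc.graph import build_graph, find_highway
from yeastbkmc.params import Parameters
from yeastbkmc.perturb import run_screen
from yeastbkmc.population import asynchronous_cycles
from yeastbkmc.rules import WILD_TYPE

SEED = 0


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def wt_graph():
    return build_graph(WILD_TYPE, include_start_edge=False)


@pytest.fixture(scope="session")
def wt_graph_start():
    return build_graph(WILD_TYPE, include_start_edge=True)


@pytest.fixture(scope="session")
def highway(wt_graph_start):
    return find_highway(wt_graph_start)


@pytest.fixture(scope="session")
def screen5000():
    """Full robustness screen: 5000 reps per perturbation + exact oracle."""
    return run_screen(n_reps=5000, seed=SEED, with_exact=True)


@pytest.fixture(scope="session")
def slow_growth_cycles():
    """Asynchronous population at mass-doubling time 150 min."""
    params = Parameters().with_mass_doubling_time(150)
    return asynchronous_cycles(params=params, n_founders=40, horizon=1200,
                               burn_in=400, seed=SEED)


@pytest.fixture(scope="session")
def default_cycles():
    """Asynchronous population at the default growth rate."""
    return asynchronous_cycles(n_founders=40, horizon=700, burn_in=400,
                               seed=SEED)
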