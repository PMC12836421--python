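import numpy as np
import pandas as pd
import pytest

from delhit import SimulationSpec, simulate, worked_example_fixture


def small_spec(seed: int = 3, **over) -> SimulationSpec:
    """Desk-scale campaign used by unit and property tests (fast)."""
    kw = dict(n_compounds=8_000, bb_sizes=(25, 20, 16), depth=12_000,
              n_actives=10, seed=seed)
    kw.update(over)
    return SimulationSpec(**kw)


@pytest.fixture(scope="session")
def small_campaign():
    """(CountMatrix, SelectionManifest, truth) for an 8k-compound campaign."""
    return simulate(small_spec())


@pytest.fixture(scope="session")
def worked_matrix():
    return worked_example_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
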