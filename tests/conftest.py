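import numpy as np
import pytest

from varens import design, observer


@pytest.fixture(scope="session")
def e1_design():
    return design.preset("E1", seed=7)


@pytest.fixture(scope="session")
def e3_design():
    return design.preset("E3", seed=7)


@pytest.fixture(scope="session")
def afc_table(e1_design):
    """Small simulated 2-AFC table: 8 unbiased observers through E1."""
    observers = observer.make_observers(8, {"sigma": 3.0, "lapse": 0.0}, seed=11)
    return observer.simulate_experiment(e1_design, observers)


@pytest.fixture(scope="session")
def adjustment_table(e3_design):
    """Small simulated adjustment table: 8 linear-distortion observers through E3."""
    observers = observer.make_observers(
        8,
        {"distortion": "linear", "a": 4.23, "b": 0.72, "sigma": 1.0, "lapse": 0.0},
        seed=13,
    )
    return observer.simulate_experiment(e3_design, observers)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
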