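import numpy as np
import pytest

import odeident as oi


@pytest.fixture(scope="session")
def twocomp():
    return oi.get_model("twocomp")


@pytest.fixture(scope="session")
def betacasein():
    return oi.get_model("betacasein")


@pytest.fixture(scope="session")
def betacasein_reduced():
    return oi.get_model("betacasein_reduced")


@pytest.fixture(scope="session")
def methanogenesis():
    return oi.get_model("methanogenesis")


@pytest.fixture(scope="session")
def methanogenesis_reduced():
    return oi.get_model("methanogenesis_reduced")


@pytest.fixture(scope="session")
def monod_haldane():
    return oi.get_model("monod_haldane")


# ---------------------------------------------------------------------------
# shared structural results (exact symbolic computations, reused across tests)


@pytest.fixture(scope="session")
def betacasein_structural(betacasein):
    return oi.test_local_identifiability(betacasein)


@pytest.fixture(scope="session")
def methano_two_output(methanogenesis):
    setup = oi.ObservationSetup(("xH2", "ng_H2"))
    return oi.test_local_identifiability(methanogenesis, setup)


@pytest.fixture(scope="session")
def methano_four_output(methanogenesis):
    setup = oi.ObservationSetup(("xH2", "ng_H2", "ng_CO2", "ng_CH4"))
    return oi.test_local_identifiability(methanogenesis, setup)


# ---------------------------------------------------------------------------
# shared simulated data


@pytest.fixture(scope="session")
def monod_grid():
    return np.linspace(0.0, 50.0, 40)


@pytest.fixture(scope="session")
def monod_input():
    return oi.ConstantInput(20.0)


@pytest.fixture(scope="session")
def monod_truth():
    return {"k": 2.0, "kI": 50.0}


@pytest.fixture(scope="session")
def monod_noisefree(monod_haldane, monod_truth, monod_grid, monod_input):
    return oi.generate_synthetic_data(
        monod_haldane, monod_truth, monod_grid, monod_input, sigma=0.0, seed=0
    )


@pytest.fixture(scope="session")
def betacasein_truth():
    # Km > kI so the reduced-model map (b1, b2) is positive
    return {"k": 1.0, "Km": 3.0, "kI": 1.5}


@pytest.fixture(scope="session")
def betacasein_noisefree(betacasein, betacasein_truth):
    return oi.generate_synthetic_data(
        betacasein, betacasein_truth, np.linspace(0.0, 30.0, 25),
        sigma=0.0, seed=0,
    )
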