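import numpy as np
import pytest

from dermapk import defaults
from dermapk.ivrt import FranzCellConfig
from dermapk.pkpd import EmaxParams, ErrorModel, PopulationModel


@pytest.fixture(scope="session")
def forms():
    return defaults.example_formulations()


@pytest.fixture(scope="session")
def cell():
    return defaults.default_cell()


@pytest.fixture(scope="session")
def skin():
    return defaults.default_skin()


@pytest.fixture(scope="session")
def transport():
    return defaults.default_transport()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pd_truth():
    """Generating population model for PD recovery checks (shrinking response).

    BSV sits on the parameters the design identifies strongly (Emax via the
    saturating tail, E0 via the baseline); per-subject EC50 is heavily
    shrunk under proportional error, so its variability is not a recovery
    target.
    """
    return PopulationModel(
        theta_pop=EmaxParams(emax=-8.0, ec50=50.0, e0=20.0, n=1.0),
        omega2={"emax": 0.04, "e0": 0.0625},
        error=ErrorModel(b=0.08),
        sigmoidicity=False,
    )


@pytest.fixture(scope="session")
def pd_exposure():
    """Exposure anchoring baseline (0), bracketing EC50 and reaching saturation."""
    t = np.array([0.0, 2.0, 4.0, 8.0, 12.0, 18.0, 24.0, 32.0, 40.0, 48.0])
    c = np.array([0.0, 10.0, 25.0, 40.0, 60.0, 85.0, 120.0, 180.0, 280.0, 400.0])
    return t, c
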