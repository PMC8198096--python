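import numpy as np
import pytest

from folfiri_tme.dosing import Regimen
from folfiri_tme.model import StateVector
from folfiri_tme.parameterization import derive_all
from folfiri_tme.simulation import DEFAULT_EVAL_DAYS, simulate


@pytest.fixture(scope="session")
def derived():
    """Default-config parameter sets: (BaselineParams, TreatmentParams, DrugScaling)."""
    return derive_all()


@pytest.fixture(scope="session")
def baseline(derived):
    return derived[0]


@pytest.fixture(scope="session")
def treatment(derived):
    return derived[1]


@pytest.fixture(scope="session")
def scaling(derived):
    return derived[2]


@pytest.fixture(scope="session")
def median_regimen():
    return Regimen()


@pytest.fixture(scope="session")
def median_trajectory(derived, median_regimen):
    """Nine-year treated trajectory from steady-state initial conditions."""
    base, treat, scal = derived
    return simulate(StateVector.ones(), base, treat, median_regimen, scal,
                    horizon=3285.0, eval_days=DEFAULT_EVAL_DAYS)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
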