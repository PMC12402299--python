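import numpy as np
import pytest

from arfeedback import InitialConditions, ParameterSet, SimulationGrid
from arfeedback.fitting import DEFAULT_BOUNDS
from arfeedback.models import PARAM_NAMES
from arfeedback.synthetic import REFERENCE_PARAMS


@pytest.fixture(scope="session")
def reference_params() -> ParameterSet:
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def default_init() -> InitialConditions:
    return InitialConditions()


@pytest.fixture(scope="session")
def coarse_grid() -> SimulationGrid:
    """Hourly reporting over 22 h; fast enough for search-heavy tests."""
    return SimulationGrid.hourly(22)


def random_parameter_set(rng: np.random.Generator) -> ParameterSet:
    """Draw a valid parameter set log-uniformly within the default
    per-parameter bounds (fast/slow decay pair ordered)."""
    values = {}
    for name in PARAM_NAMES:
        lo, hi = DEFAULT_BOUNDS[name]
        values[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if values["k_deg_p7_fast"] < values["k_deg_p7_slow"]:
        values["k_deg_p7_fast"], values["k_deg_p7_slow"] = (
            values["k_deg_p7_slow"], values["k_deg_p7_fast"])
    return ParameterSet(**values)
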