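import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from pbpkddi import (DoseEvent, DoseRegimen, ModelConfig,
                     default_rat_parameters)
from pbpkddi.model import simulate


@pytest.fixture(scope="session")
def registry():
    return default_rat_parameters()


@pytest.fixture(scope="session")
def cfg(registry):
    phys, drugs, minimal = registry
    return ModelConfig(physiology=phys, drugs=drugs, minimal=minimal)


@pytest.fixture(scope="session")
def control_regimen():
    return DoseRegimen([DoseEvent("PA", "iv_bolus", 2.5, basis="salt")])


@pytest.fixture(scope="session")
def ddi_regimen():
    return DoseRegimen([
        DoseEvent("PA", "iv_bolus", 2.5, basis="salt", start=0.0),
        DoseEvent("cimetidine", "iv_bolus", 25.0, basis="base", start=-10.0),
    ])


@pytest.fixture(scope="session")
def study_grid():
    """Dense grid with sub-minute post-bolus sampling out to 24 h."""
    return np.array(sorted(
        set(np.geomspace(0.02, 1.0, 40))
        | set(np.linspace(0.0, 1440.0, 289))
        | {1.0, 5.0, 15.0, 30.0, 60.0, 120.0, 180.0, 240.0, 360.0, 480.0}))


@pytest.fixture(scope="session")
def control_result(cfg, control_regimen, study_grid):
    return simulate(cfg, control_regimen, 1440.0, t_eval=study_grid)


@pytest.fixture(scope="session")
def ddi_result(cfg, ddi_regimen, study_grid):
    return simulate(cfg, ddi_regimen, 1440.0, t_eval=study_grid)
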