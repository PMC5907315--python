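import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from neurocalc import ModelParameters, make_scenario, simulate

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def pathology_traj():
    """Full pathology run (amyloid feedback on, t_end=1000)."""
    sc = make_scenario("pathology")
    return simulate(sc.params, sc.init, sc.stim, sc.solver,
                    scenario_name=sc.name)


@pytest.fixture(scope="session")
def nopath_traj():
    """Healthy run (amyloid pathway disabled, t_end=500)."""
    sc = make_scenario("no_pathology")
    return simulate(sc.params, sc.init, sc.stim, sc.solver,
                    scenario_name=sc.name)


@pytest.fixture(scope="session")
def rest_traj():
    """No stimulus, no amyloid: the unperturbed resting cell."""
    sc = make_scenario("no_pathology")
    stim = dataclasses.replace(sc.stim, amplitude=0.0)
    return simulate(sc.params, sc.init, stim, sc.solver,
                    scenario_name="rest")
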