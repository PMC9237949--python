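import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from nksignal.core import SimulationSpec, simulate
from nksignal.fcepsilonri import tsang_scenario
from nksignal.pathway import rajagopalan_scenario


@pytest.fixture(scope="session")
def tsang_run():
    """Tsang-protocol cascade integrated at tight tolerances (shared:
    conservation, plateau and acceptance checks all read this)."""
    model, _ = tsang_scenario()
    spec = SimulationSpec(t_start=0.0, t_end=3600.0, n_points=361,
                          rel_tol=1e-9, abs_tol=1e-9)
    return model, simulate(model, spec)


@pytest.fixture(scope="session")
def rajagopalan_run():
    """Full composite pathway over the 60000 s horizon (shared between the
    pathway behaviour tests and the acceptance checks; this is the long
    integration of the suite)."""
    model, spec = rajagopalan_scenario()
    return model, simulate(model, spec)
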