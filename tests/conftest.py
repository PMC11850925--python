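import pytest
from hypothesis import HealthCheck, settings

import cifsim as cs

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design2():
    """Reference element: f* = 1.00e-3, cutoff between LYM and MON."""
    return cs.design_element(1.0e-3, target_fr=20.0)


@pytest.fixture(scope="session")
def design4():
    """Larger-cutoff element: f* = 1.70e-3."""
    return cs.design_element(1.7e-3, target_fr=20.0)


@pytest.fixture(scope="session")
def constant_f_design():
    """Constant-fraction reference mode: fixed widths, f = 1e-3 per side."""
    return cs.design_element(1.0e-3, width_rule="fixed", target_fr=20.0)


@pytest.fixture(scope="session")
def human_sample():
    return cs.human_blood(seed=11)


@pytest.fixture(scope="session")
def spiked_sample():
    return cs.spiked_blood(seed=11)
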