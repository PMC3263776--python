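import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def alpe_route():
    from endurosim.routes import make_alpe_dhuez_route

    return make_alpe_dhuez_route()


@pytest.fixture(scope="session")
def rider():
    from endurosim.cycling import RiderParams

    return RiderParams()


@pytest.fixture(scope="session")
def body_model():
    """Reference-subject body model; set points solved once per session."""
    from endurosim.body import load_default_model

    model = load_default_model()
    model.set_points  # force the steady-state solve here
    return model


@pytest.fixture(scope="session")
def ck_params():
    from endurosim.ck import load_default_params

    return load_default_params()
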