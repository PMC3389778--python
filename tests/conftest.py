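import numpy as np
import pytest

from gpmyo import cell
from gpmyo.params import Parameters, load_reference


@pytest.fixture(scope="session")
def p() -> Parameters:
    return load_reference()


@pytest.fixture(scope="session")
def parr(p) -> np.ndarray:
    return p.as_array()


@pytest.fixture(scope="session")
def y1hz() -> np.ndarray:
    """Shipped end-diastolic state from long 1 Hz pre-pacing."""
    return cell.load_initial_state()


@pytest.fixture(scope="session")
def beat_1hz(p, y1hz):
    """One steady-state 1 Hz beat at 1-ms sampling (shared, read-only)."""
    y, _ = cell.pace_to_steady_state(1000.0, p, y1hz, max_beats=50)
    return cell.simulate_pacing(p, y, 1000.0, 1)


from hypothesis import HealthCheck, settings as _settings

_settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture])
_settings.load_profile("ci")
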