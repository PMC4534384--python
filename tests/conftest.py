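import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gridnav as gn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sys3():
    """The canonical three-module system: scales {50, 30, 20} cm."""
    return gn.canonical_system()


@pytest.fixture(scope="session")
def sys2():
    """Two-module system of the phase-precession example: {30, 20} cm."""
    return gn.two_module_system()


@pytest.fixture(scope="session")
def axis_loc(sys3):
    """Build a Location from axis coordinates (u, v) of a system."""

    def _make(system, u, v=0.0):
        xy = system.basis @ np.array([float(u), float(v)])
        return gn.Location(float(xy[0]), float(xy[1]))

    return _make
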