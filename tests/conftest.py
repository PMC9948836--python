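import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def water():
    from cemamc.materials import water as _w

    return _w()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


def make_big_disc_geometry(xcse_factor: float = 1.0, shell_r: float = 0.5):
    """A fatter water scoring disc (r = h/2 = 0.5 cm) at 5 cm depth: enough
    analog cavity events at a few 10^4 histories to give the XCSE
    unbiasedness comparisons real statistical power."""
    from cemamc.geometry import Cylinder, GeometryModel, Region
    from cemamc.materials import MATERIALS

    water = MATERIALS["water"]
    phantom = Region(1, water, 1.0, 0.010, is_phantom=True)
    z_det = -15.0 + 5.0
    bodies = []
    if shell_r > 0 and xcse_factor > 1:
        bodies.append(
            Cylinder((0, 0, z_det), 0.5 + shell_r, 0.5 + shell_r,
                     Region(2, water, xcse_factor, 0.010))
        )
    bodies.append(
        Cylinder((0, 0, z_det), 0.5, 0.5,
                 Region(2 + len(bodies), water, xcse_factor, 0.010, is_scoring_cavity=True))
    )
    return GeometryModel((15.0, 15.0, 15.0), phantom, tuple(bodies), name="big_disc")
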