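import numpy as np
import pytest

from npcroute.geometry import NPCGeometry, RouteModel


@pytest.fixture(scope="session")
def geometry():
    return NPCGeometry()


@pytest.fixture()
def peripheral_route():
    return RouteModel(mean_radius=41.0)


def assert_close(actual, expected, atol=0.0, rtol=1e-7, msg=""):
    np.testing.assert_allclose(actual, expected, atol=atol, rtol=rtol, err_msg=msg)
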