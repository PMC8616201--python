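import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ipdtplan as ip
from ipdtplan.tissue_optics import OpticalProperties, TissueTable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table():
    return ip.default_tissue_table()


@pytest.fixture(scope="session")
def absorber_table():
    """Background plus a purely absorbing medium (mu_a = 0.5/mm, mu_s = 0)."""
    return TissueTable(
        {0: OpticalProperties(0.0, 0.0, 0.0, 1.0), 1: OpticalProperties(0.5, 0.0, 0.0)},
        names={0: "background", 1: "absorber"},
        version="test-absorber",
    )


@pytest.fixture(scope="session")
def enhancing_grid_small():
    """Homogeneous enhancing-tumor cube, 40 mm on a side."""
    return ip.homogeneous_phantom(ip.TissueLabel.ENHANCING, (40, 40, 40), 1.0)


@pytest.fixture(scope="session")
def fast_phantom():
    spec = ip.PhantomSpec.fast()
    return ip.generate_phantom(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210635)
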