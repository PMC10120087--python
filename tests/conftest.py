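import numpy as np
import pytest

from tfflim import DetectorConfig, GateProfile, SystemConfig


@pytest.fixture(scope="session")
def cfg():
    """Default system configuration (t_c = 0.59 ns, y = 10, 6 replicas)."""
    return SystemConfig()


@pytest.fixture(scope="session")
def det():
    """Default detector (DQE 0.2, readout 8 e-, dark 0.03 e-/s, CIC 0)."""
    return DetectorConfig()


@pytest.fixture(scope="session")
def small_cfg():
    """Tiny 3-replica system for brute-force/finite-difference checks."""
    return SystemConfig(n_replicas=3, y=2, replica_weights=(0.5, 0.3, 0.2))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def rect_cfg(t_start=0.0, width=10.0, **kw):
    gate = GateProfile(shape="rectangular", t_start=t_start, width=width,
                       edge_sigma=0.0)
    return SystemConfig(gate=gate, **kw)
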