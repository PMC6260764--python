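import numpy as np
import pytest

from bbfse import (
    WALL_TISSUE,
    default_timing,
    design_vfa,
    velocity_sweep,
)


@pytest.fixture(scope="session")
def timing():
    """Healthy-subject protocol timing: ESP2 3.0 ms, 8 startup + 35 acquired, TE_eff 30 ms."""
    return default_timing()


@pytest.fixture(scope="session")
def wall_train(timing):
    """Auto-plateau constant-signal train designed for the vessel-wall tissue."""
    return design_vfa(WALL_TISSUE, timing, "auto")


@pytest.fixture(scope="session")
def blood_sweep(timing, wall_train):
    """Default 0-100 mm/s (1 mm/s) blood velocity sweep of the designed train."""
    return velocity_sweep(wall_train, timing)


@pytest.fixture(scope="session")
def short_timing():
    """Small train (4 startup + 8 acquired) for fast design/property tests."""
    return default_timing(n_acquired=8, n_startup=4, te_eff=30.0)
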