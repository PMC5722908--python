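import numpy as np
import pytest

import stepmd as sm
from stepmd.trajectory import Frame


@pytest.fixture(scope="session")
def docking_system():
    return sm.make_domain_docking_model(seed=0)


@pytest.fixture(scope="session")
def docking_system_no_ion():
    return sm.make_domain_docking_model(ion_present=False, seed=0)


@pytest.fixture(scope="session")
def double_well_system():
    """Barrier 4 kT double well: V(x) = 4(x² − 1)², wells at ±1."""
    return sm.make_analytic_landscape("double_well_1d", a=4.0, b=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def finite_difference_forces(system, coords, h=1e-6):
    """Central-difference force oracle, independent of the analytic path."""
    coords = np.asarray(coords, dtype=float)
    out = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for k in range(3):
            xp = coords.copy()
            xm = coords.copy()
            xp[i, k] += h
            xm[i, k] -= h
            ep, _ = sm.compute_forces(system, xp)
            em, _ = sm.compute_forces(system, xm)
            out[i, k] = -(ep - em) / (2.0 * h)
    return out


def make_frame(coords, time=0.0):
    return Frame(time=time, coords=np.asarray(coords, dtype=float))
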