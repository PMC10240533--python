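import numpy as np
import pytest

from trcdsim import SpectralGrid, Trajectory, build_trcd, pro_reference
from trcdsim.dynamics import GeneratorConfig, generate_ensemble


def make_trajectory(
    traj_id="toy",
    n=6,
    dt=1.0,
    hop_at=None,
    phi1=-60.0,
    phi2=-60.0,
    ring_open=True,
    energies=(4.0, 4.8),
    rotatory=(100.0, -10.0),
):
    """Small hand-built trajectory; scalar phi/energies are broadcast."""
    times = np.arange(n) * dt
    if hop_at is None:
        state = np.zeros(n, int)
    else:
        state = (times < hop_at).astype(int)
    open_arr = np.zeros(n, bool)
    if ring_open:
        open_arr[state == 0] = True
    phi1 = np.broadcast_to(np.asarray(phi1, float), (n,)).copy()
    phi2 = np.broadcast_to(np.asarray(phi2, float), (n,)).copy()
    e = np.broadcast_to(np.asarray(energies, float), (n, len(energies))).copy()
    r = np.broadcast_to(np.asarray(rotatory, float), (n, len(rotatory))).copy()
    return Trajectory(traj_id, times, state, phi1, phi2, open_arr, e, r)


@pytest.fixture(scope="session")
def grid():
    return SpectralGrid.default()


@pytest.fixture(scope="session")
def preset_ensemble():
    """The paper-calibration preset ensemble at the canonical test seed."""
    return generate_ensemble(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def preset_matrix(preset_ensemble, grid):
    ref = pro_reference(grid, 0.5)
    return build_trcd(preset_ensemble, grid, lw_ev=0.5, stride=10,
                      mode="add", reference=ref)
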