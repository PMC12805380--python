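import numpy as np
import pytest

from supermoco.phantom import PhantomSpec, generate_phantom, simulate_acquisition
from supermoco.trajectory import generate_vdcaspr, soft_gated_binning


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_truth():
    """8^3 moving phantom with 2 bins and 2 coils."""
    spec = PhantomSpec(grid_shape=(8, 8, 8), n_coils=2, n_bins=2, n_heartbeats=10,
                       motion_amplitude_vox=1.5, seed=5)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def small_problem(small_truth):
    """Acquisition, plan and data for the 8^3 phantom (undersampled)."""
    traj = generate_vdcaspr((8, 8), 1.5, 10, 20, seed=1)
    raw, _ = simulate_acquisition(small_truth, traj)
    plan = soft_gated_binning(raw.trajectory(), small_truth.breathing_signal, 2,
                              hr_grid_yz=(8, 8))
    return small_truth, raw, plan


@pytest.fixture(scope="session")
def static_truth():
    spec = PhantomSpec(grid_shape=(8, 16, 16), n_coils=1, n_bins=2, n_heartbeats=8,
                       motion_amplitude_vox=0.0, seed=3)
    return generate_phantom(spec)


def dense_matrix(apply_op, n, shape, m=None, dtype=complex):
    """Materialize a linear operator column by column from basis vectors."""
    cols = []
    for i in range(n):
        e = np.zeros(n, dtype=dtype)
        e[i] = 1.0
        cols.append(np.asarray(apply_op(e.reshape(shape))).ravel())
    return np.stack(cols, axis=1)
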