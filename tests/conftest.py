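import numpy as np
import pytest

from essdyn.synthetic import SyntheticSpec, generate
from essdyn.trajectory import Frame, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-size study conditions: 3 replicas x 31 frames of 40 residues."""
    return SyntheticSpec(n_residues=40, frames_per_replica=31, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate(small_spec)


def make_ca_trajectory(coords, replica_ids=None, times=None, aligned=False):
    """Trajectory from an (F, N, 3) array of C-alpha coordinates."""
    coords = np.asarray(coords, dtype=float)
    F = coords.shape[0]
    replica_ids = replica_ids if replica_ids is not None else [0] * F
    times = times if times is not None else list(range(F))
    frames = [
        Frame.from_ca_coords(coords[i], time_ns=times[i], replica_id=replica_ids[i])
        for i in range(F)
    ]
    return Trajectory(
        frames=frames, n_residues=coords.shape[1], snapshot_interval_ns=1.0,
        aligned=aligned,
    )
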