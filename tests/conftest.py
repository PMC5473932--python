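import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mdrin.io import Topology, Trajectory


def ca_topology(residue_indices, residue_names=None):
    n = len(residue_indices)
    return Topology(
        residue_indices=np.asarray(residue_indices, dtype=int),
        residue_names=np.full(n, "GLY") if residue_names is None else residue_names,
        atom_names=np.full(n, "CA"),
        elements=np.full(n, "C"),
    )


def ca_trajectory(coords, residue_indices=None):
    """Trajectory of Ca pseudo-atoms from an (F, N, 3) array."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    if residue_indices is None:
        residue_indices = np.arange(1, n + 1)
    return Trajectory(topology=ca_topology(residue_indices), coordinates=coords)


def random_rigid_transform(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    shift = rng.normal(scale=10.0, size=3)
    return rot, shift


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
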