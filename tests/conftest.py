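import numpy as np
import pytest

from gmmreff import (
    AtomicModel,
    DensityMap,
    GMMState,
    ToySpec,
    make_ground_truth_map,
    make_toy_model,
)


def single_atom_model(bwidth=1.0, z=6, position=(0.0, 0.0, 0.0)) -> AtomicModel:
    return AtomicModel(
        serial=[1],
        element=["C"],
        atomic_number=[z],
        chain_id=["A"],
        residue_index=[1],
        residue_name=["GLY"],
        atom_name=["CA"],
        positions=np.array([position], dtype=float),
        bwidth=[bwidth],
    )


def centered_grid(n=16, voxel=1.0) -> DensityMap:
    origin = -0.5 * (n - 1) * voxel * np.ones(3)
    return DensityMap(np.zeros((n, n, n)), voxel, origin)


@pytest.fixture
def small_grid():
    return centered_grid(16, 1.0)


@pytest.fixture
def toy_spec():
    return ToySpec(n_residues=8, b_range=(0.6, 1.4), noise_level=0.05, seed=3)


@pytest.fixture
def toy_model(toy_spec):
    return make_toy_model(toy_spec)


@pytest.fixture
def toy_map(toy_model, toy_spec):
    """(experimental map, generating truth state) for the toy chain."""
    return make_ground_truth_map(toy_model, toy_spec)


@pytest.fixture
def random_state(small_grid):
    """A small random mixture state on the 16³ grid, with background."""
    rng = np.random.default_rng(7)
    n = 4
    model = AtomicModel(
        serial=np.arange(1, n + 1),
        element=["C"] * n,
        atomic_number=[6, 7, 8, 6],
        chain_id=["A"] * n,
        residue_index=np.arange(1, n + 1),
        residue_name=["GLY"] * n,
        atom_name=["CA"] * n,
        positions=rng.uniform(-3, 3, (n, 3)),
        bwidth=rng.uniform(0.5, 1.5, n),
    )
    return GMMState(model, background=0.3)
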