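import numpy as np
import pytest

from svrsr.core import ImageGrid, RigidTransform, Slice, Volume
from svrsr.simulator import SimulationSpec, make_phantom, simulate_acquisition


def random_rigid(rng, max_rot=np.pi, max_trans=50.0) -> RigidTransform:
    return RigidTransform.from_params([
        *rng.uniform(-max_rot, max_rot, 3), *rng.uniform(-max_trans, max_trans, 3)])


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(40.0, 1.0, seed=7)


@pytest.fixture(scope="session")
def small_acquisition():
    """3 stacks, 12 slices each, mild corruption; session-cached."""
    vol = make_phantom(36.0, 1.0, seed=3)
    spec = SimulationSpec(slices_per_stack=12, n_displaced=1, n_corrupted=1,
                          seed=3)
    stacks, truth = simulate_acquisition(vol, spec)
    return vol, spec, stacks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_slice(values, spacing=1.0, thickness=3.0, origin=(0.0, 0.0, 0.0),
               direction=None, transform=None, mask=None) -> Slice:
    values = np.asarray(values, dtype=float)
    grid = ImageGrid((*values.shape, 1), (spacing, spacing, thickness),
                     origin, np.eye(3) if direction is None else direction)
    return Slice(values, grid, thickness, transform=transform, mask=mask)


def make_volume(values, spacing=1.0, origin=(0.0, 0.0, 0.0)) -> Volume:
    values = np.asarray(values, dtype=float)
    return Volume(ImageGrid(values.shape, (spacing,) * 3, origin), values)
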