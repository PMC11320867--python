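import numpy as np
import pytest

from sctqa.grids import BinaryStructure, ImageGrid
from sctqa.phantom import ArtefactSpec, PhantomSpec, generate_phantom


def make_structure(grid, voxels, name="a", modality="CT"):
    """Structure from an explicit voxel-index list (tiny enumerated cases)."""
    mask = np.zeros(grid.shape, dtype=bool)
    for v in voxels:
        mask[v] = True
    return BinaryStructure(name=name, modality=modality, grid=grid, mask=mask)


@pytest.fixture
def unit_grid():
    return ImageGrid(spacing=(1, 1, 1), origin=(0, 0, 0), shape=(8, 8, 8), frame_id="t")


def small_spec(**kwargs) -> PhantomSpec:
    """A reduced head used by unit tests; acceptance tests use defaults."""
    base = dict(
        head_radii_mm=(34.0, 38.0, 30.0),
        scalp_thickness_mm=4.0,
        skull_thickness_mm=5.0,
        ctv_radius_mm=10.0,
        pad_mm=6.0,
        artefacts=(ArtefactSpec("1a", thickness_mm=3.0, radius_mm=4.0),),
        cbct_shifts_mm=((0.0, 0.0, 0.0),),
        seed=11,
    )
    base.update(kwargs)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_phantom_1a():
    return generate_phantom(small_spec())
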