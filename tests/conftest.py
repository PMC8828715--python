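import numpy as np
import pytest

from radiofuse.core import VolumeWithMask
from radiofuse.synthcohort import PhantomSpec, PlantedLink, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def ball_phantom():
    """Digital ball of radius 10 mm at unit spacing."""
    spec = PhantomSpec(grid_shape=(25, 25, 25), semi_axes=(10, 10, 10))
    return generate_phantom(spec, seed=2)


@pytest.fixture(scope="session")
def textured_phantom():
    spec = PhantomSpec(grid_shape=(32, 32, 32), semi_axes=(11, 9, 12),
                       texture_scale=80.0)
    return generate_phantom(spec, seed=5)


@pytest.fixture()
def cube_vm():
    """3x3x3 foreground cube centred in a 7x7x7 grid, constant intensity."""
    mask = np.zeros((7, 7, 7), dtype=bool)
    mask[2:5, 2:5, 2:5] = True
    intens = np.where(mask, 2048.0, 0.0)
    return VolumeWithMask(intens, mask, (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def tiny_cohort():
    """12-patient cohort with two planted links, small grids for speed."""
    links = [
        PlantedLink("LINK00", "firstorder.mean", 0.6),
        PlantedLink("LINK01", "shape.volume_mm3", 0.9),
    ]
    return generate_cohort(12, 40, links, seed=11, grid_shape=(28, 28, 28))
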