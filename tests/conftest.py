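import numpy as np
import pytest

from nervestereo.grid import SectionPlane
from nervestereo.scene import ScenePhantom, SceneSpec
from nervestereo.shapes import Pose, make_sphere
from nervestereo.voxelize import voxelize


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def disc_section(radius: float, center=(0.6, 0.6), n: int = 120, dx: float = 0.01):
    """A SectionPlane whose mask is a disc (pixel-centre membership)."""
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    mask = ((jj + 0.5) * dx - center[0]) ** 2 + (
        (ii + 0.5) * dx - center[1]
    ) ** 2 <= radius**2
    return SectionPlane(image=mask.astype(np.uint16), spacing=(dx, dx))


@pytest.fixture
def unit_sphere_stack():
    """Lazily voxelized unit sphere centred in a 3 μm box (10 nm / 100 nm)."""
    ph = make_sphere(1.0, pose=Pose(translation=(1.5, 1.5, 1.5)))
    scene = SceneSpec(
        phantoms=(ScenePhantom(ph, 1, "phantom"),), bounds=((0, 0, 0), (3, 3, 3))
    )
    return voxelize(scene, (0.01, 0.01, 0.1), lazy=True)
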