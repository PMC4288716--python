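import numpy as np
import pytest

from morphomech.template_gen import DomeSpec, build_dome, build_icosphere
from morphomech.tissue_mesh import TissueMesh

# unit cube: 8 vertices, 6 outward-wound quad walls, one cell
CUBE_VERTS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)
CUBE_WALLS = [
    [0, 3, 2, 1],   # bottom (z = 0), normal -z
    [4, 5, 6, 7],   # top (z = 1), normal +z
    [0, 1, 5, 4],   # y = 0
    [1, 2, 6, 5],   # x = 1
    [2, 3, 7, 6],   # y = 1
    [3, 0, 4, 7],   # x = 0
]


def make_cube(scale: float = 1.0, shift=(0.0, 0.0, 0.0)) -> TissueMesh:
    return TissueMesh(CUBE_VERTS * scale + np.asarray(shift, float),
                      [list(w) for w in CUBE_WALLS],
                      [list(range(6))], region_labels={0: "cell"})


@pytest.fixture
def cube_mesh() -> TissueMesh:
    return make_cube()


@pytest.fixture(scope="session")
def small_dome() -> TissueMesh:
    """35-cell dome, cheap enough for per-test mechanics."""
    return build_dome(DomeSpec(radius=1.0, layers=2, resolution=8))


@pytest.fixture(scope="session")
def icosphere() -> TissueMesh:
    return build_icosphere(radius=1.0, subdivisions=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
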