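import numpy as np
import pytest

from morpho3d.synthetic import ShapeSpec, make_mesh, make_volume


@pytest.fixture(scope="session")
def icosphere4():
    """Unit-test sphere: r=10, subdivision 4 (fine; ~1% of analytic)."""
    return make_mesh(ShapeSpec("icosphere", {"radius": 10.0, "subdivisions": 4}))


@pytest.fixture(scope="session")
def icosphere2():
    """Coarse sphere for graph-heavy tests (162 vertices)."""
    return make_mesh(ShapeSpec("icosphere", {"radius": 10.0, "subdivisions": 2}))


@pytest.fixture(scope="session")
def unit_cube():
    return make_mesh(ShapeSpec("cube", {"edge": 1.0}))


@pytest.fixture(scope="session")
def cylinder():
    return make_mesh(
        ShapeSpec("cylinder", {"radius": 3.0, "height": 20.0, "sections": 128})
    )


@pytest.fixture(scope="session")
def torus():
    return make_mesh(ShapeSpec("torus", {"major_radius": 10.0, "minor_radius": 2.0}))


@pytest.fixture(scope="session")
def ball_volume20():
    return make_volume(ShapeSpec("ball_volume", {"radius": 20.0}))


@pytest.fixture(scope="session")
def tube_volume():
    return make_volume(ShapeSpec("tube_volume", {"radius": 4.0, "length": 60.0}))


@pytest.fixture(scope="session")
def y_tube_volume():
    return make_volume(ShapeSpec("y_tube_volume", {"radius": 4.0, "arm_length": 30.0}))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
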