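import numpy as np
import pytest
import trimesh

from swell3d import TriangleMesh, generate_head


def icosphere_mesh(subdivisions=3, radius=10.0):
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices, dtype=np.float64),
                        np.asarray(ico.faces, dtype=np.int64))


@pytest.fixture(scope="session")
def ico3():
    """Icosphere r=10 mm, subdivision 3 (642 vertices, 1280 faces)."""
    return icosphere_mesh(3, 10.0)


@pytest.fixture(scope="session")
def ico4():
    """Icosphere r=10 mm, subdivision 4 (2562 vertices, 5120 faces)."""
    return icosphere_mesh(4, 10.0)


@pytest.fixture(scope="session")
def head_landmarks():
    """Default synthetic head (ellipsoid 70x90x100 mm) with landmarks."""
    return generate_head()


@pytest.fixture()
def head(head_landmarks):
    return head_landmarks[0].copy()


@pytest.fixture()
def landmarks(head_landmarks):
    return head_landmarks[1]
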