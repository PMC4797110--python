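import numpy as np
import pytest

from protshape import TriangleMesh, icosphere, torus, saddle_patch


@pytest.fixture(scope="session")
def sphere4():
    """Unit icosphere, subdivision 4 (2562 vertices), with its analytic oracle."""
    return icosphere(1.0, 4)


@pytest.fixture(scope="session")
def sphere3():
    return icosphere(1.0, 3)


@pytest.fixture(scope="session")
def torus_mesh():
    return torus(2.0, 0.5, 48, 24)


@pytest.fixture(scope="session")
def saddle41():
    return saddle_patch(1.0, 41)


@pytest.fixture
def tetrahedron():
    """Unit-edge regular tetrahedron: the smallest closed triangle mesh."""
    v = np.array([
        [1, 1, 1],
        [1, -1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
    ], dtype=float) / np.sqrt(2)  # edge length 2
    v /= 2.0  # edge length 1
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(v, f, name="tetra")


@pytest.fixture
def cube():
    """Axis-aligned unit cube as 12 consistently outward triangles."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float)
    quads = [
        (0, 1, 3, 2), (4, 6, 7, 5),  # x = 0, x = 1
        (0, 4, 5, 1), (2, 3, 7, 6),  # y = 0, y = 1
        (0, 2, 6, 4), (1, 5, 7, 3),  # z = 0, z = 1
    ]
    f = []
    for a, b, c, d in quads:
        f += [(a, b, c), (a, c, d)]
    return TriangleMesh(v, np.array(f), name="cube")


@pytest.fixture
def mobius_strip():
    """Triangulated Mobius band: the canonical non-orientable surface."""
    n = 12
    u = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = []
    for t in u:
        for s in (-0.3, 0.3):
            r = 1 + s * np.cos(t / 2)
            pts.append([r * np.cos(t), r * np.sin(t), s * np.sin(t / 2)])
    v = np.array(pts)
    f = []
    for i in range(n):
        j = (i + 1) % n
        a, b = 2 * i, 2 * i + 1
        if j == 0:
            c, d = 1, 0  # half-twist: rails swap at the seam
        else:
            c, d = 2 * j, 2 * j + 1
        f += [(a, b, c), (b, d, c)]
    return TriangleMesh(v, np.array(f), name="mobius")
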