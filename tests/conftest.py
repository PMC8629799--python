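import numpy as np
import pytest

from mirrorsym import PhantomSpec, TriangleMesh, make_cup_pair


@pytest.fixture
def cube():
    """Unit cube with outward-facing winding (8 vertices, 12 faces)."""
    v = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z=0), normal -z
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # front (y=0)
            [2, 3, 7], [2, 7, 6],  # back
            [1, 2, 6], [1, 6, 5],  # right (x=1)
            [3, 0, 4], [3, 4, 7],  # left
        ]
    )
    return TriangleMesh(v, f, provenance="cube")


@pytest.fixture(scope="session")
def coarse_pair():
    """Perfectly symmetric phantom pair at coarse resolution (fast)."""
    return make_cup_pair(PhantomSpec(seed=7, mesh_resolution=2.0))


@pytest.fixture(scope="session")
def coarse_mesh(coarse_pair):
    return coarse_pair.right


def random_surface_mesh(rng, n_points=60, scale=10.0, offset=(0.0, 0.0, 0.0)):
    """Random closed triangulated surface: the convex hull of random points."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n_points, 3)) * scale + np.asarray(offset)
    hull = ConvexHull(pts)
    vert, faces, _ = np.unique(hull.simplices), hull.simplices, None
    remap = np.full(len(pts), -1, dtype=np.int64)
    remap[vert] = np.arange(len(vert))
    return TriangleMesh(pts[vert], remap[faces], provenance="hull")
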