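import numpy as np
import pytest

from cortexdev.mesh import SurfaceMesh, make_icosphere


@pytest.fixture(scope="session")
def icosahedron():
    return make_icosphere(0, 1.0)


@pytest.fixture(scope="session")
def icosphere2():
    return make_icosphere(2, 1.0)


@pytest.fixture(scope="session")
def icosphere3():
    return make_icosphere(3, 1.0)


def random_sphere_mesh(n_vertices: int, seed: int) -> SurfaceMesh:
    """Connected triangulated mesh: convex hull of random points on a sphere."""
    from scipy.spatial import ConvexHull

    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_vertices, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    hull = ConvexHull(pts)
    return SurfaceMesh(vertices=pts, triangles=hull.simplices)


def bellman_ford_oracle(mesh: SurfaceMesh, seeds) -> np.ndarray:
    """Brute-force multi-source shortest-path distances by edge relaxation."""
    e = mesh.edges()
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    dist = np.full(mesh.n_vertices, np.inf)
    dist[list(seeds)] = 0.0
    for _ in range(mesh.n_vertices):
        changed = False
        for (i, j), wij in zip(e, w):
            if dist[i] + wij < dist[j]:
                dist[j] = dist[i] + wij
                changed = True
            if dist[j] + wij < dist[i]:
                dist[i] = dist[j] + wij
                changed = True
        if not changed:
            break
    return dist
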