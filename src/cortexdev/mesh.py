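"""Triangulated surface meshes: container type, icosphere generator, file I/O.

Meshes are plain vertex/triangle arrays.  The edge graph (undirected, weighted
by Euclidean edge length) is exposed as a ``scipy.sparse`` matrix because both
the geodesic machinery and the parcellation grower operate on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

__all__ = ["SurfaceMesh", "make_icosphere", "read_mesh", "write_mesh"]


@dataclass
class SurfaceMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    triangles : (m, 3) int array
        Vertex-index triples.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be an (m, 3) array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        t = self.triangles
        if t.min(initial=0) < 0 or (self.n_triangles and t.max() >= self.n_vertices):
            raise ValueError("triangle indices out of range")
        if np.any(
            (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
        ):
            raise ValueError("degenerate triangle: repeated vertex index")
        v = self.vertices
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
        if np.any(areas <= 0):
            raise ValueError("degenerate triangle: zero area")
        n_comp, _ = connected_components(self.edge_graph(), directed=False)
        if n_comp != 1:
            raise ValueError(f"edge graph is disconnected ({n_comp} components)")

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) array with i < j."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_graph(self) -> sparse.csr_matrix:
        """Symmetric sparse adjacency weighted by Euclidean edge length."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = self.n_vertices
        g = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return g.tocsr()


# Icosahedron with unit circumradius; golden-ratio construction.
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def make_icosphere(subdivisions: int, radius: float) -> SurfaceMesh:
    """Subdivided icosahedron projected onto a sphere.

    Vertex count is ``10 * 4**subdivisions + 2``; triangle count is
    ``20 * 4**subdivisions``.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if subdivisions < 0:
        raise ValueError(f"subdivisions must be >= 0, got {subdivisions}")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return SurfaceMesh(vertices=verts * radius, triangles=faces)


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    """Split each triangle into four; midpoints shared across faces."""
    midpoint_cache: dict[tuple[int, int], int] = {}
    new_verts = list(verts)

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = midpoint_cache.get(key)
        if idx is None:
            idx = len(new_verts)
            new_verts.append((verts[i] + verts[j]) / 2.0)
            midpoint_cache[key] = idx
        return idx

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(new_verts), np.array(new_faces, dtype=np.int64)


def write_mesh(mesh: SurfaceMesh, path: str) -> None:
    """Write a mesh as OFF (``.off``) or GIFTI surface (``.gii``/``.surf.gii``)."""
    if path.endswith(".off"):
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    elif path.endswith(".gii"):
        import nibabel as nib

        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, path)
    else:
        raise ValueError(f"unsupported mesh format: {path}")


def read_mesh(path: str) -> SurfaceMesh:
    """Read a mesh from OFF or GIFTI surface."""
    if path.endswith(".off"):
        with open(path) as fh:
            tokens = fh.read().split()
        if tokens[0] != "OFF":
            raise ValueError("not an OFF file")
        nv, nt = int(tokens[1]), int(tokens[2])
        pos = 4
        verts = np.array(tokens[pos : pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        tris = np.empty((nt, 3), dtype=np.int64)
        for i in range(nt):
            cnt = int(tokens[pos])
            if cnt != 3:
                raise ValueError("only triangular faces supported")
            tris[i] = [int(tokens[pos + 1]), int(tokens[pos + 2]), int(tokens[pos + 3])]
            pos += 4
        return SurfaceMesh(vertices=verts, triangles=tris)
    if path.endswith(".gii"):
        import nibabel as nib

        img = nib.load(path)
        verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        return SurfaceMesh(vertices=np.asarray(verts, float), triangles=np.asarray(tris))
    raise ValueError(f"unsupported mesh format: {path}")
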