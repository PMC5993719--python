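"""Low-level 3D geometry: triangle meshes, closest-point queries, axis angles.

All coordinates are physical micrometres.  Points are ``(x, y, z)`` triples;
voxel-index to micrometre conversion happens at I/O, never here.

Angles between an axis (an undirected line, e.g. a nucleus long axis) and a
surface normal are reported in degrees in [0, 90]: 0 means the axis is along
the normal (radial), 90 means it lies in the tangent plane (parallel to the
surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .errors import DegenerateInputError, EmptyInputError

__all__ = [
    "TriangleMesh",
    "closest_point_on_triangle",
    "closest_surface_point",
    "angle_to_normal",
    "convex_hull_mesh",
]


@dataclass
class TriangleMesh:
    """Triangulated surface with per-face outward unit normals.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in µm.
    faces : (m, 3) int array
        Vertex indices of each triangle.
    face_normals : (m, 3) float array
        Unit outward normal of each face.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_normals: np.ndarray
    # cached per-face vertex arrays for vectorised queries
    _tri: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.intp)
        self.face_normals = np.asarray(self.face_normals, dtype=float)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise DegenerateInputError("face index out of range")
        norms = np.linalg.norm(self.face_normals, axis=1)
        if self.face_normals.size and not np.allclose(norms, 1.0, atol=1e-9):
            raise DegenerateInputError("face normals must have unit length")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Return an (m, 3, 3) array of per-face vertex coordinates."""
        if self._tri is None or self._tri.shape[0] != len(self.faces):
            self._tri = self.vertices[self.faces]
        return self._tri

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def max_outside_distance(self, p: np.ndarray) -> float:
        """Largest signed distance of ``p`` to any face plane.

        Non-positive for points inside a convex mesh (up to numerics).
        """
        p = np.asarray(p, dtype=float)
        a = self.triangles()[:, 0, :]
        return float(np.max(np.einsum("ij,ij->i", self.face_normals, p - a)))

    def contains(self, p: np.ndarray, tol: float = 1e-9) -> bool:
        """True if ``p`` is inside or on the (convex) mesh within ``tol`` µm."""
        return self.max_outside_distance(p) <= tol


def _check_triangle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> None:
    cross = np.cross(b - a, c - a)
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1.0)
    if np.linalg.norm(cross) <= 1e-12 * scale * scale:
        raise DegenerateInputError("degenerate (collinear) triangle")


def closest_point_on_triangle(
    p, a, b, c
) -> tuple[np.ndarray, float]:
    """Closest point of a closed triangle ``abc`` to ``p`` and its distance (µm).

    Classifies ``p`` against the triangle's Voronoi regions (vertex, edge,
    interior) and returns the minimiser; this is the standard exact
    closed-form solution, no iteration involved.
    """
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    _check_triangle(a, b, c)
    q = _closest_points_all_triangles(np.stack([a, b, c])[None, :, :], p)[0]
    return q, float(np.sqrt(((p - q) ** 2).sum()))


def _closest_points_all_triangles(tri: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorised closest point of ``p`` on every triangle.

    Parameters
    ----------
    tri : (m, 3, 3) array of triangle vertices.
    p : (3,) query point.

    Returns
    -------
    (m, 3) array of closest points (one per triangle).
    """
    a = tri[:, 0, :]
    b = tri[:, 1, :]
    c = tri[:, 2, :]
    ab = b - a
    ac = c - a
    ap = p[None, :] - a
    bp = p[None, :] - b
    cp = p[None, :] - c
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    def assign(mask: np.ndarray, value: np.ndarray) -> None:
        nonlocal done
        m = mask & ~done
        if m.any():
            out[m] = value[m] if value.ndim == 2 else value
            done |= m

    with np.errstate(divide="ignore", invalid="ignore"):
        assign((d1 <= 0) & (d2 <= 0), a)
        assign((d3 >= 0) & (d4 <= d3), b)
        t = d1 / (d1 - d3)
        assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t[:, None] * ab)
        assign((d6 >= 0) & (d5 <= d6), c)
        t = d2 / (d2 - d6)
        assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t[:, None] * ac)
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        assign(
            (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
            b + t[:, None] * (c - b),
        )
        # mirror the scalar code's arithmetic (reciprocal then multiply) so
        # the vectorised and looped paths agree bit-for-bit
        denom = 1.0 / (va + vb + vc)
        v = vb * denom
        w = vc * denom
        assign(np.ones(len(a), dtype=bool), a + ab * v[:, None] + ac * w[:, None])
    return out


def closest_surface_point(
    mesh: TriangleMesh, p
) -> tuple[np.ndarray, int, float]:
    """Closest point of a mesh surface to ``p``.

    Returns ``(point, face_index, distance_um)``.  The minimum is taken over
    every face; equidistant faces are broken by the lowest face index.
    """
    if mesh.n_faces == 0:
        raise EmptyInputError("mesh has no faces")
    p = np.asarray(p, dtype=float)
    pts = _closest_points_all_triangles(mesh.triangles(), p)
    d = np.sqrt(((p[None, :] - pts) ** 2).sum(axis=1))
    i = int(np.argmin(d))  # argmin returns the first (lowest-index) minimum
    return pts[i], i, float(d[i])


def angle_to_normal(axis, normal) -> float:
    """Angle in degrees in [0, 90] between an undirected axis and a normal.

    Both arguments are normalised internally and the absolute value of the
    cosine is used, so the result is invariant to sign flips of either
    vector: axes are lines, not arrows.  90 means the axis lies in the
    tangent plane (parallel to the surface).
    """
    u = np.asarray(axis, dtype=float)
    n = np.asarray(normal, dtype=float)
    nu = np.linalg.norm(u)
    nn = np.linalg.norm(n)
    if nu == 0.0 or nn == 0.0:
        raise DegenerateInputError("zero vector has no direction")
    cos = abs(u @ n) / (nu * nn)
    return float(np.degrees(np.arccos(np.clip(cos, 0.0, 1.0))))


def convex_hull_mesh(points: np.ndarray) -> TriangleMesh:
    """Triangulated convex hull of a 3D point set, outward face normals.

    Raises :class:`DegenerateInputError` for fewer than 4 points or a
    coplanar configuration.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise DegenerateInputError("points must be an (n, 3) array")
    if len(points) < 4:
        raise DegenerateInputError("convex hull needs at least 4 points")
    try:
        hull = ConvexHull(points)
    except Exception as exc:  # qhull raises QhullError on flat inputs
        raise DegenerateInputError(f"degenerate point set for convex hull: {exc}")
    # reindex to hull vertices only
    remap = -np.ones(len(points), dtype=np.intp)
    remap[hull.vertices] = np.arange(len(hull.vertices))
    vertices = points[hull.vertices]
    faces = remap[hull.simplices]
    normals = hull.equations[:, :3].copy()
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    # qhull normals already point outward; double-check orientation against
    # the centroid and flip any stragglers (paranoia for near-degenerate faces)
    centroid = vertices.mean(axis=0)
    tri = vertices[faces]
    outward = np.einsum("ij,ij->i", normals, tri[:, 0, :] - centroid[None, :])
    normals[outward < 0] *= -1.0
    return TriangleMesh(vertices=vertices, faces=faces, face_normals=normals)
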