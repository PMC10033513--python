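"""Validated volumetric primitives on closed triangle meshes.

All volumetric quantities (volume, centre of mass) are computed exactly for
polyhedra by signed-tetrahedron decomposition against an arbitrary origin
(the divergence theorem), so results are independent of tessellation and of
the decomposition origin.  The canonical length unit is metres; meshes read
from disk are converted on load according to the declared unit.

Coordinate convention used throughout the package: +x cranial, +y left,
+z dorsal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

logger = logging.getLogger(__name__)

_UNIT_TO_METRES = {"m": 1.0, "cm": 0.01, "mm": 0.001}


class MeshError(ValueError):
    """Raised for geometrically invalid meshes or degenerate inputs."""


@dataclass
class TriMesh:
    """A triangle mesh: ``vertices`` (n, 3) float array in metres and
    ``faces`` (m, 3) integer array, counter-clockwise when viewed from
    outside."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError("face indices out of range")

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    @property
    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def bbox_diagonal(self) -> float:
        lo, hi = self.bounds
        return float(np.linalg.norm(hi - lo))

    def translated(self, t) -> "TriMesh":
        return TriMesh(self.vertices + np.asarray(t, dtype=float), self.faces.copy())

    def transformed(self, rotation, translation=(0.0, 0.0, 0.0)) -> "TriMesh":
        """Rigid-body transform v -> R v + t.  Improper rotations
        (det < 0, i.e. reflections) reverse the face winding so the surface
        stays outward-oriented."""
        R = np.asarray(rotation, dtype=float)
        verts = self.vertices @ R.T + np.asarray(translation, dtype=float)
        faces = self.faces.copy()
        if np.linalg.det(R) < 0:
            faces = faces[:, ::-1]
        return TriMesh(verts, faces)

    def flipped(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces[:, ::-1].copy())


@dataclass
class MassProperties:
    """Volume (m^3), centre of mass (m) and, when a density was supplied,
    mass (kg) of a closed mesh."""

    volume: float
    com: np.ndarray
    mass: float | None = None


@dataclass
class MeshReport:
    watertight: bool
    orientation_consistent: bool
    n_components: int
    messages: list = field(default_factory=list)
    repaired: bool = False

    @property
    def ok(self) -> bool:
        return self.watertight and self.orientation_consistent


def _edge_maps(faces: np.ndarray):
    """Directed edge multiset of the face list, keyed by undirected edge."""
    edges: dict[tuple[int, int], list[int]] = {}
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            edges.setdefault(key, []).append(1 if a < b else -1)
    return edges


def signed_volume(mesh: TriMesh) -> float:
    """Signed volume by the divergence theorem; positive for outward-
    oriented closed surfaces."""
    v = mesh.vertices - mesh.vertices.mean(axis=0)  # local origin: stability
    f = mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def validate_mesh(mesh: TriMesh, repair: bool = True) -> MeshReport:
    """Check watertightness, winding consistency and connectivity.

    A globally inverted mesh (consistent winding but negative signed
    volume) is repaired in place by flipping every face; the repair is
    logged and recorded on the report.  Non-manifold edges (shared by more
    than two faces) are a hard failure, and mixed winding is reported but
    never silently repaired.
    """
    messages: list[str] = []
    areas = np.linalg.norm(
        np.cross(
            mesh.vertices[mesh.faces[:, 1]] - mesh.vertices[mesh.faces[:, 0]],
            mesh.vertices[mesh.faces[:, 2]] - mesh.vertices[mesh.faces[:, 0]],
        ),
        axis=1,
    )
    if np.any(areas == 0.0):
        messages.append(f"{int((areas == 0).sum())} degenerate (zero-area) faces")

    edges = _edge_maps(mesh.faces)
    bad = [e for e, d in edges.items() if len(d) > 2]
    if bad:
        raise MeshError(f"non-manifold edges (shared by >2 faces): {bad[:20]}")

    watertight = all(len(d) == 2 for d in edges.values())
    if not watertight:
        n_open = sum(1 for d in edges.values() if len(d) != 2)
        messages.append(f"{n_open} boundary edges: mesh is not closed")
    orientation_consistent = all(
        sum(d) == 0 for d in edges.values() if len(d) == 2
    )
    if not orientation_consistent:
        messages.append("inconsistent (mixed) face winding")

    # connected components over the face adjacency graph via union-find
    parent = list(range(len(mesh.vertices)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for f in mesh.faces:
        a = find(f[0])
        for v in f[1:]:
            b = find(v)
            parent[b] = a
    used = np.unique(mesh.faces)
    n_components = len({find(int(v)) for v in used}) if len(used) else 0

    repaired = False
    if watertight and orientation_consistent and signed_volume(mesh) < 0:
        if repair:
            mesh.faces = mesh.faces[:, ::-1]
            repaired = True
            messages.append("globally inverted mesh: all faces flipped")
            logger.info("validate_mesh: repaired globally inverted orientation")
        else:
            messages.append("globally inverted mesh (negative signed volume)")

    return MeshReport(
        watertight=watertight,
        orientation_consistent=orientation_consistent,
        n_components=n_components,
        messages=messages,
        repaired=repaired,
    )


def mass_properties(mesh: TriMesh, density: float | None = None) -> MassProperties:
    """Exact volume and centre of mass of a closed mesh.

    The mesh is decomposed into signed tetrahedra (origin, face); summing
    signed volumes and signed-volume-weighted tetrahedron centroids gives
    the polyhedron's volume and centroid exactly.  ``density`` (kg m^-3),
    when given, must be positive and yields ``mass = volume * density``.
    """
    if density is not None and density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    edges = _edge_maps(mesh.faces)
    if any(len(d) > 2 for d in edges.values()):
        raise MeshError("non-manifold mesh")
    if not all(len(d) == 2 and sum(d) == 0 for d in edges.values()):
        raise MeshError("open or inconsistently wound mesh: volume undefined")

    # decompose against a point near the mesh (analytically the result is
    # origin-independent; numerically a far origin causes catastrophic
    # cancellation between large signed tetrahedra)
    ref = mesh.vertices.mean(axis=0)
    v = mesh.vertices - ref
    f = mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    tet_vol = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    vol = float(tet_vol.sum())
    if vol < 0:  # globally inverted; report as positive solid
        tet_vol = -tet_vol
        vol = -vol
    if vol <= 0:
        raise MeshError("mesh has non-positive volume")
    centroids = (a + b + c) / 4.0  # fourth tetrahedron vertex is the reference
    com = (tet_vol[:, None] * centroids).sum(axis=0) / vol + ref
    return MassProperties(
        volume=vol,
        com=com,
        mass=vol * density if density is not None else None,
    )


def convex_hull(points: np.ndarray) -> TriMesh:
    """Minimum convex hull of a 3-D point set as an outward-oriented
    closed triangle mesh (Quickhull, via scipy's qhull bindings)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise MeshError(
            f"convex hull needs >= 4 points in 3-D, got shape {pts.shape}"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise MeshError(
            "degenerate input: points are coplanar or otherwise rank-deficient "
            f"({exc.__class__.__name__})"
        ) from exc
    verts = pts[hull.vertices]
    remap = {old: new for new, old in enumerate(hull.vertices)}
    faces = np.array([[remap[i] for i in s] for s in hull.simplices], dtype=np.int64)
    mesh = TriMesh(verts, faces)
    # qhull does not guarantee simplex orientation: orient each face outward
    # from the hull centroid, then the whole surface is consistent.
    centre = verts.mean(axis=0)
    a, b, c = (
        mesh.vertices[faces[:, 0]],
        mesh.vertices[faces[:, 1]],
        mesh.vertices[faces[:, 2]],
    )
    normals = np.cross(b - a, c - a)
    inward = np.einsum("ij,ij->i", normals, a - centre) < 0
    faces[inward] = faces[inward][:, ::-1]
    return TriMesh(mesh.vertices, faces)


def points_in_hull(points: np.ndarray, hull: TriMesh, rtol: float = 1e-9) -> np.ndarray:
    """Half-space containment test of points against every hull facet, with
    tolerance scaled by the hull's bounding-box diagonal."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = hull.vertices[hull.faces[:, 0]]
    b = hull.vertices[hull.faces[:, 1]]
    c = hull.vertices[hull.faces[:, 2]]
    normals = np.cross(b - a, c - a)
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    tol = rtol * hull.bbox_diagonal
    # outward normals: a point is inside iff (p - a) . n <= tol for all facets
    d = pts @ normals.T - np.einsum("ij,ij->i", a, normals)
    return np.all(d <= tol, axis=1)


def contains_points(mesh: TriMesh, points: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Point-in-mesh test by ray-crossing parity (Moeller-Trumbore),
    vectorised over points.

    Casts one ray per point along a fixed oblique direction and counts
    triangle crossings; an odd count means inside.  This is an entirely
    different computation from the signed-tetrahedron mass properties, so
    the two can cross-check each other.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.array([0.123456789, 0.5773502691896258, 0.8086421375291])
    d = d / np.linalg.norm(d)
    # orthonormal basis perpendicular to the ray direction
    b1 = np.cross(d, [1.0, 0.0, 0.0])
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(d, b1)

    v = mesh.vertices
    f = mesh.faces
    a = v[f[:, 0]]
    e1 = v[f[:, 1]] - a
    e2 = v[f[:, 2]] - a
    # 2-D barycentric solve in the plane perpendicular to d
    E = np.stack(
        [[e1 @ b1, e2 @ b1], [e1 @ b2, e2 @ b2]]
    )  # (2, 2, T)
    det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
    n = np.cross(e1, e2)
    nd = n @ d
    ok = (np.abs(det) > 1e-30) & (np.abs(nd) > 1e-30)
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    inv_nd = np.where(ok, 1.0 / np.where(ok, nd, 1.0), 0.0)
    M00 = E[1, 1] * inv_det
    M01 = -E[0, 1] * inv_det
    M10 = -E[1, 0] * inv_det
    M11 = E[0, 0] * inv_det
    a1, a2 = a @ b1, a @ b2
    c = np.einsum("ij,ij->i", n, a)

    inside = np.zeros(len(pts), dtype=bool)
    for lo in range(0, len(pts), chunk):
        p = pts[lo:lo + chunk]
        s1 = (p @ b1)[:, None] - a1[None, :]
        s2 = (p @ b2)[:, None] - a2[None, :]
        u = M00 * s1 + M01 * s2
        w = M10 * s1 + M11 * s2
        t = (c[None, :] - p @ n.T) * inv_nd
        hit = ok[None, :] & (u >= 0.0) & (w >= 0.0) & (u + w <= 1.0) & (t > 0.0)
        inside[lo:lo + chunk] = (hit.sum(axis=1) % 2) == 1
    return inside


def monte_carlo_volume(mesh: TriMesh, n_samples: int = 10_000, seed: int = 0):
    """Monte-Carlo containment estimate of the enclosed volume: uniform
    samples in the bounding box, counted by :func:`contains_points`.
    Returns ``(estimate, standard_error)``."""
    rng = np.random.default_rng(seed)
    lo, hi = mesh.bounds
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    frac = contains_points(mesh, pts).mean()
    box = float(np.prod(hi - lo))
    se = box * np.sqrt(frac * (1.0 - frac) / n_samples)
    return box * frac, se


def scale_to_volume(mesh: TriMesh, target_volume: float, centre) -> TriMesh:
    """Isotropically scale about ``centre`` so the volume equals
    ``target_volume``.  When ``centre`` is the mesh CoM the CoM is
    unchanged."""
    if target_volume <= 0:
        raise ValueError(f"target volume must be positive, got {target_volume}")
    current = mass_properties(mesh).volume
    factor = (target_volume / current) ** (1.0 / 3.0)
    centre = np.asarray(centre, dtype=float)
    return TriMesh(centre + factor * (mesh.vertices - centre), mesh.faces.copy())


def load_mesh(path, units: str = "m") -> TriMesh:
    """Read an OBJ/PLY/STL mesh and convert vertices to metres."""
    import trimesh as _trimesh

    if units not in _UNIT_TO_METRES:
        raise ValueError(f"unknown unit {units!r}; expected one of mm|cm|m")
    tm = _trimesh.load_mesh(str(path), process=False)
    return TriMesh(np.asarray(tm.vertices) * _UNIT_TO_METRES[units],
                   np.asarray(tm.faces))


def save_mesh(mesh: TriMesh, path) -> None:
    """Write a mesh (OBJ/PLY/STL by extension); vertices are metres."""
    import trimesh as _trimesh

    _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(str(path))
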