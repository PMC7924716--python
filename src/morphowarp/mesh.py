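"""Triangle-mesh geometry: OBJ I/O, closest-point projection, tangent frames.

All coordinates are in millimetres.  Vertex indices are 0-based internally;
the 1-based (or negative, relative) indices of the Wavefront OBJ format are
converted at the I/O boundary.

The closest-point query is exact: every candidate triangle that could attain
the minimum distance is tested with an exact point-to-triangle routine.  The
candidate set comes from a k-d tree on the vertices — the distance to the
nearest vertex is itself an upper bound on the surface distance (vertices lie
on the surface), and any triangle whose closest point is within that bound
must have a vertex within bound + longest-edge-length of the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyMeshError, GeometryError, MeshFormatError

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@dataclass
class LoadReport:
    """What happened while reading a mesh file."""

    n_vertices: int
    n_faces: int
    n_degenerate_dropped: int


@dataclass
class SurfacePoint:
    """A point constrained to a mesh surface.

    ``position`` equals the barycentric combination of the face's vertices.
    """

    face_index: int
    barycentric: np.ndarray  # (3,) non-negative, sums to 1
    position: np.ndarray  # (3,) mm

    def check(self, mesh: "TriangleMesh", tol: float = 1e-9) -> None:
        tri = mesh.vertices[mesh.faces[self.face_index]]
        recon = self.barycentric @ tri
        if np.linalg.norm(recon - self.position) > tol:
            raise GeometryError("surface point inconsistent with barycentric coords")


@dataclass
class TriangleMesh:
    """A triangle surface mesh (vertices in mm, faces as 0-based index triples)."""

    vertices: np.ndarray  # (V, 3) float64
    faces: np.ndarray  # (F, 3) int64
    load_report: Optional[LoadReport] = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) == 0:
            raise EmptyMeshError("mesh has zero faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshFormatError("face references a vertex index out of range")

    # ------------------------------------------------------------------ #
    @classmethod
    def clean(cls, vertices, faces) -> "TriangleMesh":
        """Build a mesh, dropping degenerate (zero-area) faces.

        The number of dropped faces is recorded in ``load_report``.
        """
        vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        keep = _nondegenerate_mask(vertices, faces)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d degenerate faces", dropped)
        faces = faces[keep]
        if len(faces) == 0:
            raise EmptyMeshError("mesh has zero non-degenerate faces")
        report = LoadReport(len(vertices), len(faces), dropped)
        return cls(vertices, faces, load_report=report)

    # -- cached geometry ------------------------------------------------ #
    @property
    def triangles(self) -> np.ndarray:
        """(F, 3, 3) vertex coordinates per face."""
        if "triangles" not in self._cache:
            self._cache["triangles"] = self.vertices[self.faces]
        return self._cache["triangles"]

    @property
    def face_normals(self) -> np.ndarray:
        if "face_normals" not in self._cache:
            tri = self.triangles
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            self._cache["face_normals"] = n / np.where(norm == 0, 1.0, norm)
        return self._cache["face_normals"]

    @property
    def face_areas(self) -> np.ndarray:
        if "face_areas" not in self._cache:
            tri = self.triangles
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
            self._cache["face_areas"] = 0.5 * np.linalg.norm(n, axis=1)
        return self._cache["face_areas"]

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def vertex_normals(self) -> np.ndarray:
        """Angle-weighted vertex normals (unit length where defined)."""
        if "vertex_normals" not in self._cache:
            self._cache["vertex_normals"] = _angle_weighted_normals(
                self.vertices, self.faces, self.face_normals
            )
        return self._cache["vertex_normals"]

    @property
    def kdtree(self) -> cKDTree:
        if "kdtree" not in self._cache:
            self._cache["kdtree"] = cKDTree(self.vertices)
        return self._cache["kdtree"]

    @property
    def vertex_faces(self) -> list:
        """For each vertex, the list of incident face indices."""
        if "vertex_faces" not in self._cache:
            inc: list = [[] for _ in range(len(self.vertices))]
            for fi, f in enumerate(self.faces):
                for v in f:
                    inc[v].append(fi)
            self._cache["vertex_faces"] = inc
        return self._cache["vertex_faces"]

    @property
    def max_edge_length(self) -> float:
        if "max_edge" not in self._cache:
            tri = self.triangles
            e = np.stack(
                [
                    np.linalg.norm(tri[:, 1] - tri[:, 0], axis=1),
                    np.linalg.norm(tri[:, 2] - tri[:, 1], axis=1),
                    np.linalg.norm(tri[:, 0] - tri[:, 2], axis=1),
                ]
            )
            self._cache["max_edge"] = float(e.max())
        return self._cache["max_edge"]

    def submesh(self, face_indices: Sequence[int]) -> "TriangleMesh":
        """Mesh restricted to a subset of faces (vertices re-indexed)."""
        face_indices = np.asarray(face_indices, dtype=np.int64)
        faces = self.faces[face_indices]
        used = np.unique(faces)
        remap = -np.ones(len(self.vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[used], remap[faces])


def _nondegenerate_mask(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """True where a face has distinct indices and non-zero area."""
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    return distinct & (area2 > 0.0)


# ---------------------------------------------------------------------- #
# Wavefront OBJ I/O
# ---------------------------------------------------------------------- #

def read_obj(path) -> TriangleMesh:
    """Read a Wavefront OBJ triangle mesh.

    Only ``v`` and ``f`` records are used; texture/normal/material records are
    ignored.  Polygonal faces are fan-triangulated.  Negative (relative) face
    indices are resolved against the vertices defined so far, per the OBJ
    specification.  Degenerate faces are dropped and counted in the mesh's
    ``load_report``.
    """
    path = Path(path)
    vertices: list = []
    tri_faces: list = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise MeshFormatError(
                        f"{path.name}:{lineno}: vertex record needs 3 coordinates"
                    )
                try:
                    vertices.append([float(x) for x in parts[1:4]])
                except ValueError as exc:
                    raise MeshFormatError(
                        f"{path.name}:{lineno}: bad vertex coordinate ({exc})"
                    ) from None
            elif tag == "f":
                if len(parts) < 4:
                    raise MeshFormatError(
                        f"{path.name}:{lineno}: face record needs >= 3 vertices"
                    )
                idx = []
                for tok in parts[1:]:
                    head = tok.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError:
                        raise MeshFormatError(
                            f"{path.name}:{lineno}: bad face index {tok!r}"
                        ) from None
                    if i == 0:
                        raise MeshFormatError(
                            f"{path.name}:{lineno}: OBJ indices are 1-based, got 0"
                        )
                    i = i - 1 if i > 0 else len(vertices) + i
                    if i < 0 or i >= len(vertices):
                        raise MeshFormatError(
                            f"{path.name}:{lineno}: face index {tok!r} out of range"
                        )
                    idx.append(i)
                for a, b in zip(idx[1:-1], idx[2:]):  # fan triangulation
                    tri_faces.append([idx[0], a, b])
            # vt, vn, g, o, s, usemtl, mtllib ... are ignored
    if not tri_faces:
        raise EmptyMeshError(f"{path.name}: no faces found")
    return TriangleMesh.clean(np.array(vertices), np.array(tri_faces))


def write_obj(mesh: TriangleMesh, path) -> None:
    """Write ``v``/``f`` records (1-based indices, full float precision)."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------- #
# Exact closest-point projection
# ---------------------------------------------------------------------- #

def _closest_on_triangles(p: np.ndarray, tri: np.ndarray):
    """Exact closest point from ``p`` to each triangle in ``tri`` (T, 3, 3).

    Returns (points (T,3), barycentric (T,3)).  Vectorized region-based
    point-triangle test (Ericson, Real-Time Collision Detection, ch. 5).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    T = len(tri)
    bary = np.empty((T, 3))
    done = np.zeros(T, dtype=bool)

    def settle(mask, u, v, w):
        m = mask & ~done
        bary[m, 0] = u[m] if isinstance(u, np.ndarray) else u
        bary[m, 1] = v[m] if isinstance(v, np.ndarray) else v
        bary[m, 2] = w[m] if isinstance(w, np.ndarray) else w
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), 1.0, 0.0, 0.0)  # vertex a
    settle((d3 >= 0) & (d4 <= d3), 0.0, 1.0, 0.0)  # vertex b
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), 1.0 - t_ab, t_ab, 0.0)  # edge ab
    settle((d6 >= 0) & (d5 <= d6), 0.0, 0.0, 1.0)  # vertex c
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), 1.0 - t_ac, 0.0, t_ac)  # edge ac
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = np.where(den != 0, num / den, 0.0)
    settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), 0.0, 1.0 - t_bc, t_bc)
    # interior
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    settle(np.ones(T, dtype=bool), 1.0 - v - w, v, w)

    pts = np.einsum("tk,tkj->tj", bary, tri)
    return pts, bary


def closest_point(mesh: TriangleMesh, p) -> SurfacePoint:
    """Exact nearest point on the mesh surface; ties go to the lowest face index."""
    return project_points(mesh, np.asarray(p, dtype=np.float64).reshape(1, 3))[0]


def project_points(mesh: TriangleMesh, points: np.ndarray) -> list:
    """Batch exact closest-point projection. Returns a list of SurfacePoint."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    d_vert, _ = mesh.kdtree.query(points)
    radius = d_vert + mesh.max_edge_length + 1e-12
    out = []
    for p, r in zip(points, radius):
        vids = mesh.kdtree.query_ball_point(p, r)
        cand = np.unique(
            np.concatenate([np.asarray(mesh.vertex_faces[v], dtype=np.int64) for v in vids])
        )
        pts, bary = _closest_on_triangles(p, mesh.triangles[cand])
        d = np.linalg.norm(pts - p, axis=1)
        dmin = d.min()
        tie = d <= dmin + _TIE_TOL * (1.0 + dmin)
        best = cand[tie].min()
        j = int(np.where(cand == best)[0][0])
        out.append(SurfacePoint(int(best), bary[j], pts[j]))
    return out


def project_positions(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Convenience: projected world positions only, as an (N, 3) array."""
    return np.array([sp.position for sp in project_points(mesh, points)])


# ---------------------------------------------------------------------- #
# Tangent structures
# ---------------------------------------------------------------------- #

def _angle_weighted_normals(vertices, faces, face_normals) -> np.ndarray:
    tri = vertices[faces]
    normals = np.zeros_like(vertices)
    for corner in range(3):
        p0 = tri[:, corner]
        p1 = tri[:, (corner + 1) % 3]
        p2 = tri[:, (corner + 2) % 3]
        e1 = p1 - p0
        e2 = p2 - p0
        n1 = np.linalg.norm(e1, axis=1)
        n2 = np.linalg.norm(e2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cosang = np.einsum("ij,ij->i", e1, e2) / np.where(n1 * n2 == 0, 1, n1 * n2)
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(normals, faces[:, corner], face_normals * ang[:, None])
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    return normals / np.where(norm == 0, 1.0, norm)


def surface_normal(mesh: TriangleMesh, sp: SurfacePoint) -> np.ndarray:
    """Barycentrically interpolated angle-weighted vertex normal (unit)."""
    vn = mesh.vertex_normals[mesh.faces[sp.face_index]]
    n = sp.barycentric @ vn
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("zero-length interpolated normal")
    return n / norm


def surface_tangent_basis(mesh: TriangleMesh, sp: SurfacePoint):
    """Deterministic orthonormal tangent basis (u, v) at a surface point.

    u is the normalized tangential projection of the global x-axis (falling
    back to the y-axis when the normal is nearly parallel to x); v = n x u.
    """
    n = surface_normal(mesh, sp)
    for axis in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        u = axis - (axis @ n) * n
        norm = np.linalg.norm(u)
        if norm > 1e-6:
            u = u / norm
            v = np.cross(n, u)
            return u, v / np.linalg.norm(v)
    raise GeometryError("could not build a tangent basis")  # pragma: no cover


def curve_tangent(polyline: np.ndarray, i: int) -> np.ndarray:
    """Unit tangent of an ordered polyline: central difference at interior
    indices, one-sided at the endpoints."""
    polyline = np.asarray(polyline, dtype=np.float64).reshape(-1, 3)
    m = len(polyline)
    if m < 2:
        raise GeometryError("polyline needs at least 2 points")
    if i == 0:
        d = polyline[1] - polyline[0]
    elif i == m - 1:
        d = polyline[-1] - polyline[-2]
    else:
        d = polyline[i + 1] - polyline[i - 1]
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise GeometryError(f"coincident neighbours around polyline index {i}")
    return d / norm
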