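"""Rigid transforms, ultrasound-calibration chains and mesh geometry primitives.

All coordinates are right-handed and in millimetres. Ultrasound pixel
coordinates use the left-bottom corner of the slice as the origin, with the
in-plane axes u (right) and v (up) and the out-of-plane coordinate fixed at 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "PixelGrid",
    "SurfaceModel",
    "ClosestPoint",
    "compose",
    "pixel_to_probe",
    "probe_to_tracker",
    "closest_point_on_surface",
    "closest_points_on_surface",
]

_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """Raised for invalid geometric inputs (domain errors)."""


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """A proper rigid transform: orthonormal rotation (det +1) plus translation.

    Houses every transform in the guidance chain: the in-slice calibration
    T_C (pixel plane to probe space), the tracking transform T_T (probe to
    tracker space), the Procrustes initialization T_0 and the registration
    result T_R (preoperative MR space to intraoperative tracker space).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(t))):
            raise GeometryError("non-finite transform entries")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        M = np.asarray(matrix, dtype=float).reshape(4, 4)
        if not np.allclose(M[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise GeometryError("last row of homogeneous matrix must be [0,0,0,1]")
        return cls(M[:3, :3], M[:3, 3])

    @classmethod
    def from_axis_angle(
        cls,
        axis: np.ndarray,
        angle_deg: float,
        translation: np.ndarray | None = None,
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise GeometryError("zero-norm rotation axis")
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return cls(rot.as_matrix(), t)

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        max_translation: float = 50.0,
    ) -> "RigidTransform":
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls(R, t)

    # -- algebra -----------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one point (3,) or a stack of points (n, 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    @property
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return float(
            np.rad2deg(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    def relative_to(self, base: "RigidTransform") -> "RigidTransform":
        """The offset D such that self = D ∘ base."""
        return self.compose(base.invert())

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "units": "mm"}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_matrix(np.asarray(d["matrix"], dtype=float))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition a ∘ b: applying the result equals applying b, then a."""
    return a.compose(b)


@dataclass(frozen=True)
class PixelGrid:
    """Geometry of a 2D ultrasound slice.

    Pixel (0, 0) sits at the left-bottom corner; ``spacing`` converts pixel
    indices (u, v) to physical in-plane millimetres.
    """

    width: int
    height: int
    spacing: tuple[float, float]

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise GeometryError("grid dimensions must be positive")
        if min(self.spacing) <= 0:
            raise GeometryError("pixel spacing must be strictly positive")

    def pixel_to_plane(self, pixel) -> np.ndarray:
        """Physical in-plane coordinates of a pixel, out-of-plane coordinate 0."""
        u, v = float(pixel[0]), float(pixel[1])
        if not (0 <= u <= self.width and 0 <= v <= self.height):
            raise GeometryError(
                f"pixel ({u}, {v}) outside grid {self.width}x{self.height}"
            )
        return np.array([u * self.spacing[0], v * self.spacing[1], 0.0])


def pixel_to_probe(pixel, T_C: RigidTransform, grid: PixelGrid) -> np.ndarray:
    """Map a US pixel into the local probe space: y = T_C · x.

    The in-slice calibration T_C converts physical in-plane pixel coordinates
    (third coordinate 0) into the 3D space of the optical markers mounted on
    the probe.
    """
    return T_C.apply(grid.pixel_to_plane(pixel))


def probe_to_tracker(y: np.ndarray, T_T: RigidTransform) -> np.ndarray:
    """Map a probe-space point into tracker space: z = T_T · y."""
    return T_T.apply(np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# Surface meshes and closest-point queries
# ---------------------------------------------------------------------------

VALID_LABELS = ("kidney", "vessel", "skin", "lesion")


class ClosestPoint(NamedTuple):
    point: np.ndarray
    distance: float
    face_index: int


class SurfaceModel:
    """A labeled triangulated surface in millimetre coordinates.

    Kidney and lesion surfaces are expected to be watertight (closed,
    edge-manifold); vessel bundles may be a concatenation of capped tubes and
    the skin may be an open sheet.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, label: str):
        vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        if label not in VALID_LABELS:
            raise GeometryError(f"label must be one of {VALID_LABELS}, got {label!r}")
        if not np.all(np.isfinite(vertices)):
            raise GeometryError("non-finite vertex coordinates")
        if len(faces) and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise GeometryError("face indices out of range")
        self.vertices = vertices
        self.faces = faces
        self.label = label
        self._cache: dict = {}

    def __len__(self) -> int:
        return len(self.faces)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, label: str) -> "SurfaceModel":
        return cls(mesh.vertices, mesh.faces, label)

    def as_trimesh(self) -> trimesh.Trimesh:
        if "trimesh" not in self._cache:
            self._cache["trimesh"] = trimesh.Trimesh(
                self.vertices.copy(), self.faces.copy(), process=False
            )
        return self._cache["trimesh"]

    def is_watertight(self) -> bool:
        """Edge-manifold test after merging coincident vertices and dropping
        zero-area faces (marching-cubes output contains both)."""
        mesh = trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)
        mesh.merge_vertices(digits_vertex=6)
        mesh.update_faces(mesh.nondegenerate_faces())
        return bool(mesh.is_watertight)

    def transformed(self, T: RigidTransform) -> "SurfaceModel":
        return SurfaceModel(T.apply(self.vertices), self.faces, self.label)

    # precomputed structures for accelerated closest-point queries
    def _accel(self):
        if "accel" not in self._cache:
            tris = self.vertices[self.faces]  # (m, 3, 3)
            centroids = tris.mean(axis=1)
            circumradii = np.linalg.norm(tris - centroids[:, None, :], axis=2).max(
                axis=1
            )
            self._cache["accel"] = (
                cKDTree(self.vertices),
                cKDTree(centroids),
                centroids,
                circumradii,
                float(circumradii.max()) if len(circumradii) else 0.0,
                tris,
            )
        return self._cache["accel"]

    # -- IO ----------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        self.as_trimesh().export(str(path))

    @classmethod
    def load(cls, path: str | Path, label: str) -> "SurfaceModel":
        mesh = trimesh.load_mesh(str(path), process=False)
        return cls(mesh.vertices, mesh.faces, label)


def ray_mesh_intersections(
    origin: np.ndarray, direction: np.ndarray, m: SurfaceModel
) -> np.ndarray:
    """Parameters t of all ray/triangle intersections origin + t·direction,
    t ≥ 0 (Möller–Trumbore, vectorized over faces)."""
    origin = np.asarray(origin, float).reshape(3)
    direction = np.asarray(direction, float).reshape(3)
    tris = m.vertices[m.faces]
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = origin - tris[:, 0]
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", q, e2)
    eps = 1e-9
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t >= -eps)
    return np.sort(t[hit])


def points_inside_mesh(points: np.ndarray, m: SurfaceModel) -> np.ndarray:
    """Even-odd containment test for a closed mesh via ray casting."""
    points = np.asarray(points, float).reshape(-1, 3)
    # deliberately asymmetric direction: grid-aligned meshes (marching cubes)
    # put vertices on lattice lines, and a symmetric ray would graze shared
    # edges and break the parity count
    direction = np.array([0.2404871213513404, 0.7320964830620896, 0.6372194393029417])
    return np.array(
        [len(ray_mesh_intersections(p, direction, m)) % 2 == 1 for p in points]
    )


_TIE_TOL = 1e-12


def closest_point_on_surface(p: np.ndarray, m: SurfaceModel) -> ClosestPoint:
    """Exact closest point on a triangle mesh to a query point.

    A KD-tree over vertices bounds the search radius and a KD-tree over face
    centroids prefilters candidate triangles; the exact point-to-triangle
    projection then runs only on candidates whose lower distance bound does
    not exceed that radius, so the result is identical to testing every
    triangle. Ties (within 1e-12 mm) are broken by the lowest face index.
    """
    return closest_points_on_surface(np.asarray(p, float).reshape(1, 3), m)[0]


def closest_points_on_surface(points: np.ndarray, m: SurfaceModel) -> list[ClosestPoint]:
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(m.faces) == 0:
        raise GeometryError("empty mesh")
    vtree, ctree, centroids, circumradii, max_cr, tris = m._accel()
    upper, _ = vtree.query(points)  # distance to nearest vertex bounds the optimum
    out: list[ClosestPoint] = []
    for p, ub in zip(points, upper):
        cand = ctree.query_ball_point(p, ub + max_cr + 1e-9)
        cand = np.asarray(cand, dtype=np.int64)
        # keep faces whose lower bound |p-centroid| - circumradius can beat ub
        lb = np.linalg.norm(centroids[cand] - p, axis=1) - circumradii[cand]
        cand = cand[lb <= ub + 1e-9]
        cand.sort()
        sub = tris[cand]
        closest = trimesh.triangles.closest_point(sub, np.tile(p, (len(sub), 1)))
        d = np.linalg.norm(closest - p, axis=1)
        dmin = d.min()
        k = int(np.flatnonzero(d <= dmin + _TIE_TOL)[0])  # lowest face index wins
        out.append(ClosestPoint(closest[k], float(d[k]), int(cand[k])))
    return out
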