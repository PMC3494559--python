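"""Ground-truth synthetic scenes emulating an augmented-ultrasound acquisition.

A scene holds preoperative-style surface models in MR space (kidney with a
concave hilum notch, hilum-vein and IVC tubes, skin, lesions), a known rigid
MR→tracker transform, two pairs of near-orthogonal ultrasound slice planes in
tracker space with feature points sampled on the slice/surface intersection
curves, three paired anatomical landmarks, and a quasi-periodic breathing
trace. Because the truth transform is known exactly, recovery experiments can
measure registration error without the dense-ultrasound bronze standard used
on human data.

The kidney is a superellipsoid with a cylindrical notch carved from its
medial face so that the hilum landmark is geometrically identifiable; the
mesh comes from marching cubes over the implicit field, which guarantees a
watertight surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .gating import BreathTrace
from .geometry import RigidTransform, SurfaceModel
from .registration import FeaturePointSet

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "SlicePlane",
    "GenerationError",
    "generate_scene",
    "slice_contour",
    "generate_breath_trace",
    "redraw_landmarks",
]


class GenerationError(RuntimeError):
    """Raised when the requested scene geometry is infeasible."""


@dataclass(frozen=True)
class SlicePlane:
    """Pose of one ultrasound slice plane in tracker space."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        n = n / np.linalg.norm(n)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic acquisition.

    The kidney long axis is cranio-caudal (z), the medial direction +y, the
    anterior direction x; semi-axes default to 55 (z) x 30 (y) x 25 (x) mm.
    ``truth_*`` define the ground-truth MR→tracker transform. Point counts
    K2/V2 set how many contour points are picked on the kidney (all four
    slices) and on the vessel surfaces (transverse slices only);
    ``point_noise_sd`` emulates manual picking error in the slices and
    ``landmark_noise_sd`` the coarser manual landmark selection.
    """

    kidney_semiaxes: tuple[float, float, float] = (25.0, 30.0, 55.0)
    notch_radius: float = 12.0
    ivc_radius: float = 8.0
    vein_radius: float = 4.0
    skin_radius: float = 130.0
    lesion_centers: tuple[tuple[float, float, float], ...] = (
        (0.0, 0.0, 30.0),
        (0.0, 0.0, -30.0),
    )
    lesion_radius: float = 8.0
    truth_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    truth_rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    truth_rotation_deg: float = 0.0
    n_kidney_points: int = 24
    n_vessel_points: int = 10
    point_noise_sd: float = 1.0
    landmark_noise_sd: float = 2.0
    mesh_resolution: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kidney_points < 3:
            raise ValueError("need at least 3 kidney contour points (K2 >= 3)")
        if self.n_vessel_points not in (0,) and self.n_vessel_points < 3:
            raise ValueError("vessel points must be 0 or at least 3 (V2 >= 3)")
        if self.point_noise_sd < 0 or self.landmark_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if min(self.kidney_semiaxes) <= 0 or self.mesh_resolution <= 0:
            raise ValueError("geometry parameters must be positive")

    @property
    def truth(self) -> RigidTransform:
        if self.truth_rotation_deg == 0.0:
            return RigidTransform(np.eye(3), np.asarray(self.truth_translation, float))
        return RigidTransform.from_axis_angle(
            self.truth_rotation_axis, self.truth_rotation_deg, self.truth_translation
        )

    def motion_within(self, A: float = 28.0, alpha: float = 30.0) -> bool:
        """Whether the ground-truth motion respects the constraint bounds."""
        return (
            np.linalg.norm(self.truth_translation) <= A
            and abs(self.truth_rotation_deg) <= alpha
        )

    @classmethod
    def with_random_motion(
        cls,
        seed: int,
        motion_scale: float = 0.5,
        A: float = 28.0,
        alpha: float = 30.0,
        **kwargs,
    ) -> "SceneSpec":
        """Spec whose truth transform is drawn uniformly within
        ``motion_scale`` times the constraint bounds (translation norm and
        rotation angle)."""
        rng = np.random.default_rng(seed)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(-1.0, 1.0) * alpha * motion_scale
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        translation = direction * rng.uniform(0.0, A * motion_scale)
        return cls(
            truth_translation=tuple(float(x) for x in translation),
            truth_rotation_axis=tuple(float(x) for x in axis),
            truth_rotation_deg=float(angle),
            seed=int(seed),
            **kwargs,
        )


@dataclass(frozen=True)
class SyntheticScene:
    """A generated acquisition with its ground truth."""

    kidney: SurfaceModel
    vessels: SurfaceModel
    skin: SurfaceModel
    lesions: tuple[SurfaceModel, ...]
    lesion_centers: np.ndarray
    slices: tuple[SlicePlane, ...]
    features: FeaturePointSet
    features_clean: FeaturePointSet
    mr_landmarks: np.ndarray
    us_landmarks: np.ndarray
    truth: RigidTransform
    trace: BreathTrace
    spec: SceneSpec


# ---------------------------------------------------------------------------
# Implicit-surface mesh construction (cached per geometry)
# ---------------------------------------------------------------------------

_SUPERELLIPSOID_P = 2.5  # slightly boxier than an ellipsoid, kidney-like


@lru_cache(maxsize=8)
def _kidney_mesh_cached(
    semiaxes: tuple[float, float, float], notch_radius: float, resolution: float
) -> trimesh.Trimesh:
    ax, ay, az = semiaxes
    margin = 3 * resolution
    lo = np.array([-ax - margin, -ay - margin, -az - margin])
    hi = np.array([ax + margin, ay + margin, az + margin])
    ns = np.maximum(((hi - lo) / resolution).astype(int) + 1, 8)
    xs = [np.linspace(lo[i], hi[i], ns[i]) for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    p = _SUPERELLIPSOID_P
    g_se = (
        np.abs(X / ax) ** p + np.abs(Y / ay) ** p + np.abs(Z / az) ** p - 1.0
    )
    f = g_se
    if notch_radius > 0:
        # cylindrical groove along x carved into the medial (y = +ay) face
        g_cyl = ((Y - ay) ** 2 + Z**2) / notch_radius**2 - 1.0
        f = np.maximum(g_se, -g_cyl)
    spacing = tuple((hi - lo) / (ns - 1))
    verts, faces, _, _ = marching_cubes(f, level=0.0, spacing=spacing)
    verts = verts + lo
    # marching cubes emits coincident vertices and zero-area faces; merge and
    # drop them so the surface is edge-manifold
    mesh = trimesh.Trimesh(verts, faces, process=False)
    mesh.merge_vertices(digits_vertex=6)
    mesh.update_faces(mesh.nondegenerate_faces())
    if not mesh.is_watertight:
        raise GenerationError("kidney isosurface is not watertight")
    return mesh


@lru_cache(maxsize=8)
def _vessel_mesh_cached(
    medial_semiaxis: float, notch_radius: float, ivc_radius: float, vein_radius: float
) -> trimesh.Trimesh:
    y_ivc = medial_semiaxis + 27.0
    y_tip = medial_semiaxis - notch_radius / 2.0 if notch_radius > 0 else medial_semiaxis + 2.0
    ivc = trimesh.creation.cylinder(
        radius=ivc_radius, segment=[[0, y_ivc, -70.0], [0, y_ivc, 70.0]], sections=24
    )
    vein = trimesh.creation.cylinder(
        radius=vein_radius, segment=[[0, y_ivc, 0.0], [0, y_tip, 0.0]], sections=24
    )
    return trimesh.util.concatenate([ivc, vein])


@lru_cache(maxsize=8)
def _kidney_model_cached(semiaxes, notch_radius, resolution) -> SurfaceModel:
    return SurfaceModel.from_trimesh(
        _kidney_mesh_cached(semiaxes, notch_radius, resolution), "kidney"
    )


@lru_cache(maxsize=8)
def _vessel_model_cached(medial, notch_radius, ivc_radius, vein_radius) -> SurfaceModel:
    return SurfaceModel.from_trimesh(
        _vessel_mesh_cached(medial, notch_radius, ivc_radius, vein_radius), "vessel"
    )


def _build_models(spec: SceneSpec):
    # shared across scenes with identical geometry so the closest-point
    # acceleration structures are built once
    kidney = _kidney_model_cached(
        spec.kidney_semiaxes, spec.notch_radius, spec.mesh_resolution
    )
    vessels = _vessel_model_cached(
        spec.kidney_semiaxes[1], spec.notch_radius, spec.ivc_radius, spec.vein_radius
    )
    skin = SurfaceModel.from_trimesh(
        trimesh.creation.cylinder(radius=spec.skin_radius, height=280.0, sections=48),
        "skin",
    )
    lesions = tuple(
        SurfaceModel.from_trimesh(
            trimesh.creation.icosphere(subdivisions=2, radius=spec.lesion_radius).apply_translation(c),
            "lesion",
        )
        for c in spec.lesion_centers
    )
    return kidney, vessels, skin, lesions


# ---------------------------------------------------------------------------
# Slice contours
# ---------------------------------------------------------------------------


def slice_contour(plane: SlicePlane, m: SurfaceModel, n_points: int) -> np.ndarray:
    """Sample ``n_points`` evenly by arc length along the plane/mesh
    intersection curves. Returns an (n, 3) array (empty if no intersection);
    every point lies on the plane and on the mesh surface."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    section = m.as_trimesh().section(
        plane_origin=plane.origin, plane_normal=plane.normal
    )
    if section is None:
        return np.empty((0, 3))
    segments = [np.asarray(d, float) for d in section.discrete if len(d) >= 2]
    if not segments:
        return np.empty((0, 3))
    pieces, lengths = [], []
    for poly in segments:
        seg_len = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        pieces.append((poly, np.concatenate([[0.0], np.cumsum(seg_len)])))
        lengths.append(seg_len.sum())
    total = float(sum(lengths))
    if total == 0:
        return np.empty((0, 3))
    targets = (np.arange(n_points) + 0.5) / n_points * total
    out = np.empty((n_points, 3))
    offset = 0.0
    j = 0
    for poly, cum in pieces:
        while j < n_points and targets[j] <= offset + cum[-1] + 1e-12:
            s = min(targets[j] - offset, cum[-1])
            k = int(np.searchsorted(cum, s, side="right") - 1)
            k = min(k, len(poly) - 2)
            denom = cum[k + 1] - cum[k]
            frac = 0.0 if denom == 0 else (s - cum[k]) / denom
            out[j] = poly[k] + frac * (poly[k + 1] - poly[k])
            j += 1
        offset += cum[-1]
    while j < n_points:  # guard against float round-off at the curve end
        out[j] = pieces[-1][0][-1]
        j += 1
    # snap exactly onto the plane (interpolation leaves ~1e-13 residues)
    out -= ((out - plane.origin) @ plane.normal)[:, None] * plane.normal
    return out


def _tilted(base: np.ndarray, rng: np.random.Generator, max_tilt_deg: float = 4.0) -> np.ndarray:
    """A unit vector tilted away from ``base`` by a random angle <= max_tilt."""
    tilt = np.deg2rad(rng.uniform(0.0, max_tilt_deg))
    # random direction perpendicular to base
    perp = np.cross(base, rng.normal(size=3))
    while np.linalg.norm(perp) < 1e-9:
        perp = np.cross(base, rng.normal(size=3))
    perp /= np.linalg.norm(perp)
    v = math.cos(tilt) * base + math.sin(tilt) * perp
    return v / np.linalg.norm(v)


def _split(n: int, parts: int) -> list[int]:
    base, rem = divmod(n, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _hilum_landmark(kidney: SurfaceModel, spec: SceneSpec) -> np.ndarray:
    ay = spec.kidney_semiaxes[1]
    v = kidney.vertices
    if spec.notch_radius > 0:
        in_notch = ((v[:, 1] - ay) ** 2 + v[:, 2] ** 2 < (1.1 * spec.notch_radius) ** 2) & (
            v[:, 1] > 0
        )
        if in_notch.any():
            return v[in_notch].mean(axis=0)
    return v[np.argmin(np.linalg.norm(v - np.array([0.0, ay, 0.0]), axis=1))]


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Deterministic scene synthesis from a spec (all randomness seeded).

    Feature points are arc-length samples of the slice-plane intersection
    curves of the truth-transformed surfaces, plus isotropic Gaussian picking
    noise; kidney points come from all four slices, vessel points only from
    the transverse pair, matching the acquisition protocol the slices
    emulate.
    """
    rng = np.random.default_rng(spec.seed)
    kidney, vessels, skin, lesions = _build_models(spec)
    truth = spec.truth

    kidney_tra = kidney.transformed(truth)
    vessels_tra = vessels.transformed(truth)
    centroid = kidney_tra.vertices.mean(axis=0)

    # two transverse slices (normals near the cranio-caudal axis) and two
    # longitudinal slices (normals near the anterior axis), almost orthogonal
    z_hat, x_hat = np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
    planes = (
        SlicePlane(centroid - 8.0 * z_hat, _tilted(z_hat, rng)),
        SlicePlane(centroid + 8.0 * z_hat, _tilted(z_hat, rng)),
        SlicePlane(centroid - 5.0 * x_hat, _tilted(x_hat, rng)),
        SlicePlane(centroid + 5.0 * x_hat, _tilted(x_hat, rng)),
    )

    kidney_pts = []
    for plane, n in zip(planes, _split(spec.n_kidney_points, 4)):
        if n == 0:
            continue
        pts = slice_contour(plane, kidney_tra, n)
        if len(pts) == 0:
            raise GenerationError("a slice plane misses the kidney surface")
        kidney_pts.append(pts)
    kidney_pts = np.vstack(kidney_pts)

    vessel_pts = np.empty((0, 3))
    if spec.n_vessel_points:
        chunks = []
        for plane, n in zip(planes[:2], _split(spec.n_vessel_points, 2)):
            if n == 0:
                continue
            pts = slice_contour(plane, vessels_tra, n)
            if len(pts) == 0:
                raise GenerationError("a transverse slice misses the vessel surfaces")
            chunks.append(pts)
        vessel_pts = np.vstack(chunks)

    clean = FeaturePointSet(kidney_pts, vessel_pts)
    noisy = FeaturePointSet(
        kidney_pts + rng.normal(0.0, spec.point_noise_sd, kidney_pts.shape),
        vessel_pts + rng.normal(0.0, spec.point_noise_sd, vessel_pts.shape)
        if len(vessel_pts)
        else vessel_pts,
    )

    v = kidney.vertices
    mr_landmarks = np.vstack(
        [v[np.argmax(v[:, 2])], v[np.argmin(v[:, 2])], _hilum_landmark(kidney, spec)]
    )
    us_landmarks = truth.apply(mr_landmarks) + rng.normal(
        0.0, spec.landmark_noise_sd, (3, 3)
    )

    trace = generate_breath_trace(
        rate=20.0, n=80, seed=int(rng.integers(0, 2**31 - 1))
    )

    return SyntheticScene(
        kidney=kidney,
        vessels=vessels,
        skin=skin,
        lesions=lesions,
        lesion_centers=np.asarray(spec.lesion_centers, float),
        slices=planes,
        features=noisy,
        features_clean=clean,
        mr_landmarks=mr_landmarks,
        us_landmarks=us_landmarks,
        truth=truth,
        trace=trace,
        spec=spec,
    )


def redraw_landmarks(scene: SyntheticScene, seed: int) -> np.ndarray:
    """A fresh draw of the noisy ultrasound landmarks (manual re-selection),
    for repeatability studies."""
    rng = np.random.default_rng(seed)
    return scene.truth.apply(scene.mr_landmarks) + rng.normal(
        0.0, scene.spec.landmark_noise_sd, (3, 3)
    )


# ---------------------------------------------------------------------------
# Breathing trace
# ---------------------------------------------------------------------------


def generate_breath_trace(
    rate: float = 20.0,
    n: int = 80,
    period: float = 4.0,
    amplitude: float = 10.0,
    drift: float = 0.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    baseline: float = 1.0,
    phase: float = math.pi,
) -> BreathTrace:
    """Quasi-periodic probe-to-axis distance trace sampled at ``rate``.

    The waveform is baseline + amplitude·(1 − cos(2πt/period + phase))/2
    plus linear drift and Gaussian jitter, clipped at zero; its local minima
    mark simulated end-exhale pauses.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / rate
    d = baseline + 0.5 * amplitude * (1.0 - np.cos(2.0 * math.pi * t / period + phase))
    d = d + drift * t + rng.normal(0.0, noise_sd, n)
    return BreathTrace(t, np.clip(d, 0.0, None), rate)
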