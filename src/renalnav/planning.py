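"""Preoperative planning: vessel segmentation, isosurface meshing and
needle-trajectory definition with vessel-clearance checking.

The planning volume is a high-contrast steady-state MR acquisition in which
vessels stand out from the background, so one or two seeds plus an intensity
band suffice for a connected region-growing segmentation. The segmented mask
is smoothed with a 3D Gaussian and meshed by marching cubes. A trajectory is
an entry point on the skin plus a target point in the kidney; the only
computable safety rule is clearance from the large vessels (entry-site
guidance such as the intercostal window is advisory and left to the
surgeon).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import nibabel as nib
import trimesh
from scipy import ndimage
from scipy.optimize import minimize_scalar
from skimage.measure import marching_cubes

from .geometry import (
    RigidTransform,
    SurfaceModel,
    closest_points_on_surface,
    points_inside_mesh,
    ray_mesh_intersections,
)

__all__ = [
    "ScalarVolume",
    "Trajectory",
    "SeedError",
    "MeshingError",
    "region_grow",
    "mask_to_surface",
    "trajectory_clearance",
    "transfer_plan",
]


class SeedError(ValueError):
    pass


class MeshingError(ValueError):
    pass


@dataclass(frozen=True)
class ScalarVolume:
    """A scalar voxel volume with physical spacing (mm/voxel) and origin."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3 or d.size == 0:
            raise ValueError("volume must be a non-empty 3D array")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "data", d)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.data, np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ScalarVolume":
        img = nib.load(str(path))
        aff = img.affine
        return cls(
            np.asarray(img.get_fdata()),
            tuple(np.abs(np.diag(aff)[:3])),
            tuple(aff[:3, 3]),
        )


@dataclass(frozen=True)
class Trajectory:
    """Planned needle path: skin entry point and intrarenal target (mm)."""

    entry: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.entry, dtype=float).reshape(3)
        t = np.asarray(self.target, dtype=float).reshape(3)
        if np.linalg.norm(e - t) == 0:
            raise ValueError("entry and target must differ")
        object.__setattr__(self, "entry", e)
        object.__setattr__(self, "target", t)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.entry - self.target))


def region_grow(
    vol: ScalarVolume,
    seeds: list[tuple[int, int, int]],
    low: float,
    high: float,
    connectivity: int = 6,
) -> np.ndarray:
    """Seeded connected-threshold segmentation.

    Returns the union of the connected components of
    {voxel : low <= intensity <= high} that contain the seeds. Connectivity
    is 6 (face neighbours, the default) or 26.
    """
    if low > high:
        raise ValueError("low must not exceed high")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    if not seeds:
        raise SeedError("at least one seed required")
    data = vol.data
    for s in seeds:
        s = tuple(int(i) for i in s)
        if any(i < 0 or i >= n for i, n in zip(s, data.shape)):
            raise SeedError(f"seed {s} outside the volume")
        if not (low <= data[s] <= high):
            raise SeedError(f"seed {s} intensity {data[s]} outside [{low}, {high}]")
    band = (data >= low) & (data <= high)
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, _ = ndimage.label(band, structure=structure)
    wanted = {labels[tuple(int(i) for i in s)] for s in seeds}
    return np.isin(labels, sorted(wanted))


def mask_to_surface(
    mask: np.ndarray,
    vol: ScalarVolume,
    smoothing_sd: float = 1.0,
    label: str = "vessel",
) -> SurfaceModel:
    """Triangulated isosurface of a binary mask in physical coordinates.

    The 0/1 indicator is smoothed with a 3D Gaussian of ``smoothing_sd`` mm
    (0 skips smoothing) and meshed by marching cubes at level 0.5; the mask
    is zero-padded first so the surface always closes.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != vol.data.shape:
        raise ValueError("mask and volume shapes differ")
    if not mask.any():
        raise MeshingError("empty mask")
    spacing = np.asarray(vol.spacing, float)
    ind = np.pad(mask.astype(float), 1)
    if smoothing_sd > 0:
        ind = ndimage.gaussian_filter(ind, sigma=smoothing_sd / spacing)
    if ind.max() <= 0.5 or ind.min() >= 0.5:
        raise MeshingError("mask too thin to produce an isosurface at level 0.5")
    verts, faces, _, _ = marching_cubes(ind, level=0.5, spacing=tuple(spacing))
    verts = verts - spacing + np.asarray(vol.origin, float)  # undo the 1-voxel pad
    return SurfaceModel(verts, faces, label)


def _segment_point(traj: Trajectory, t: float) -> np.ndarray:
    return traj.entry + t * (traj.target - traj.entry)


def trajectory_clearance(
    traj: Trajectory, vessels: SurfaceModel, n_samples: int = 256
) -> float:
    """Minimum distance (mm) from the entry–target segment to the vessel
    surface; 0 if the segment crosses or lies inside the mesh.

    The segment is sampled densely, the surface distance evaluated at each
    sample, and the minimum refined by a bounded 1-D search around the best
    sample (the distance is continuous along the segment).
    """
    # a crossing shows up as a ray hit between the endpoints
    direction = traj.target - traj.entry
    t_hits = ray_mesh_intersections(traj.entry, direction, vessels)
    if np.any(t_hits <= 1 + 1e-9):
        return 0.0
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = traj.entry + ts[:, None] * direction
    d = np.asarray([h.distance for h in closest_points_on_surface(pts, vessels)])
    k = int(np.argmin(d))
    lo, hi = ts[max(k - 1, 0)], ts[min(k + 1, n_samples - 1)]

    def f(t: float) -> float:
        return closest_points_on_surface(_segment_point(traj, t).reshape(1, 3), vessels)[
            0
        ].distance

    res = minimize_scalar(f, bounds=(lo, hi), method="bounded")
    return float(min(d[k], res.fun))


def transfer_plan(traj: Trajectory, T_R: RigidTransform) -> Trajectory:
    """Carry a planned trajectory from MR space into tracker space."""
    return Trajectory(T_R.apply(traj.entry), T_R.apply(traj.target))
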