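"""Shared serialization: scene bundles, feature/landmark CSVs, transform and
result JSON. Meshes go through PLY/STL via trimesh, traces through CSV."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gating import BreathTrace
from .geometry import RigidTransform, SurfaceModel
from .registration import FeaturePointSet, RegistrationResult
from .synthetic import SceneSpec, SyntheticScene

__all__ = [
    "write_scene_bundle",
    "read_features_csv",
    "write_features_csv",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "write_result_json",
    "read_result_transform",
]


def _meta(seed: int | None = None, **params) -> dict:
    out = {"generator": f"renalnav {__version__}"}
    if seed is not None:
        out["seed"] = seed
    out.update(params)
    return out


def write_features_csv(path: str | Path, features: FeaturePointSet) -> None:
    pts = np.vstack([features.kidney_points, features.vessel_points])
    labels = ["kidney"] * features.k2 + ["vessel"] * features.v2
    pd.DataFrame(
        {"x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2], "label": labels}
    ).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> FeaturePointSet:
    df = pd.read_csv(path)
    xyz = df[["x", "y", "z"]].to_numpy(float)
    return FeaturePointSet(
        xyz[df["label"] == "kidney"], xyz[df["label"] == "vessel"]
    )


_LANDMARK_NAMES = ("cranial", "caudal", "hilum")


def write_landmarks_csv(
    path: str | Path, mr_landmarks: np.ndarray, us_landmarks: np.ndarray
) -> None:
    mr = np.asarray(mr_landmarks, float).reshape(3, 3)
    us = np.asarray(us_landmarks, float).reshape(3, 3)
    pd.DataFrame(
        {
            "name": _LANDMARK_NAMES,
            "mr_x": mr[:, 0],
            "mr_y": mr[:, 1],
            "mr_z": mr[:, 2],
            "us_x": us[:, 0],
            "us_y": us[:, 1],
            "us_z": us[:, 2],
        }
    ).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    mr = df[["mr_x", "mr_y", "mr_z"]].to_numpy(float)
    us = df[["us_x", "us_y", "us_z"]].to_numpy(float)
    return mr, us


def write_result_json(path: str | Path, result: RegistrationResult) -> None:
    Path(path).write_text(json.dumps({**result.to_dict(), "meta": _meta()}, indent=2))


def read_result_transform(path: str | Path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))


def write_scene_bundle(outdir: str | Path, scene: SyntheticScene) -> Path:
    """Write a scene as a directory: models/*.ply, features.csv,
    landmarks.csv, truth.json, trace.csv and spec.yaml."""
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    scene.kidney.save(outdir / "models" / "kidney.ply")
    scene.vessels.save(outdir / "models" / "vessels.ply")
    scene.skin.save(outdir / "models" / "skin.ply")
    for i, lesion in enumerate(scene.lesions):
        lesion.save(outdir / "models" / f"lesion_{i}.ply")
    write_features_csv(outdir / "features.csv", scene.features)
    write_landmarks_csv(outdir / "landmarks.csv", scene.mr_landmarks, scene.us_landmarks)
    scene.truth.to_json(outdir / "truth.json")
    scene.trace.to_csv(outdir / "trace.csv")
    spec = asdict(scene.spec)
    spec["meta"] = _meta(seed=scene.spec.seed)
    (outdir / "spec.yaml").write_text(yaml.safe_dump(spec))
    return outdir


def read_scene_spec(path: str | Path) -> SceneSpec:
    raw = yaml.safe_load(Path(path).read_text())
    raw.pop("meta", None)
    for key in ("kidney_semiaxes", "truth_translation", "truth_rotation_axis"):
        raw[key] = tuple(raw[key])
    raw["lesion_centers"] = tuple(tuple(c) for c in raw["lesion_centers"])
    return SceneSpec(**raw)
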