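"""MR-to-ultrasound rigid registration: Procrustes landmark initialization
followed by the orthogonal-slice constrained iterative closest point (OICP).

The preoperative kidney and vessel surfaces live in MR space (S_MR); the
intraoperative feature points — picked on kidney contours in two pairs of
near-orthogonal ultrasound slices and on the hilum-vein/IVC surfaces in the
transverse pair — live in tracker space (S_tra). The registration estimates
the rigid map T_R : S_MR → S_tra that brings the surfaces onto the points,
by minimizing the categorized mean squared closest-point distance

    MSE(T) = (1/K2) Σ_i d(k_i, T·kidney)² + (1/V2) Σ_i d(v_i, T·vessels)²

subject to cumulative bounds on the update relative to the initialization
T_0: the rotation offset angle stays within ±alpha and the translation
offset norm within ±A. The bounds reflect the assumption that the landmark
initialization is already close, which both speeds up the search and keeps
it out of distant local minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .geometry import (
    GeometryError,
    RigidTransform,
    SurfaceModel,
    closest_points_on_surface,
)

__all__ = [
    "FeaturePointSet",
    "OICPConfig",
    "RegistrationResult",
    "DegeneracyError",
    "procrustes_init",
    "oicp_objective",
    "oicp_register",
    "rigid_update_constrained",
]

logger = logging.getLogger(__name__)


class DegeneracyError(ValueError):
    """Raised when correspondences cannot determine a rigid transform."""


@dataclass(frozen=True)
class FeaturePointSet:
    """Manually-picked intraoperative feature points, in tracker space.

    ``kidney_points`` come from the transverse and longitudinal kidney
    contours of all four slices; ``vessel_points`` from the hilum-vein and
    IVC surfaces visible in the transverse pair. Vessel points may be absent
    (the vessel term of the objective is then dropped).
    """

    kidney_points: np.ndarray
    vessel_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        k = np.asarray(self.kidney_points, dtype=float).reshape(-1, 3)
        v = np.asarray(self.vessel_points, dtype=float).reshape(-1, 3)
        if len(k) < 3:
            raise ValueError("at least 3 kidney points required")
        object.__setattr__(self, "kidney_points", k)
        object.__setattr__(self, "vessel_points", v)

    @property
    def k2(self) -> int:
        return len(self.kidney_points)

    @property
    def v2(self) -> int:
        return len(self.vessel_points)

    def stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """All points with their per-point objective weights (1/K2, 1/V2)."""
        pts = np.vstack([self.kidney_points, self.vessel_points])
        w = np.concatenate(
            [
                np.full(self.k2, 1.0 / self.k2),
                np.full(self.v2, 1.0 / self.v2) if self.v2 else np.empty(0),
            ]
        )
        return pts, w


@dataclass(frozen=True)
class OICPConfig:
    """Constraint bounds and stopping rule of the constrained ICP.

    A: translation bound in mm; alpha: rotation bound in degrees — both
    cumulative offsets relative to the initialization T_0. h: absolute
    MSE-decrease stopping threshold in mm²; n_max: iteration cap.
    """

    A: float = 28.0
    alpha: float = 30.0
    h: float = 0.1
    n_max: int = 200

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be positive")
        if not 0 < self.alpha <= 180:
            raise ValueError("alpha must be in (0, 180] degrees")
        if self.h < 0:
            raise ValueError("h must be non-negative")
        if self.n_max < 1:
            raise ValueError("n_max must be at least 1")


@dataclass(frozen=True)
class RegistrationResult:
    """Final MR→tracker transform with the per-iteration MSE trace.

    ``mse_trace[0]`` is the objective at T_0; entry n is the objective after
    iteration n, so the trace is non-increasing. ``tracker_to_mr`` gives the
    inverse map (the direction that composes with the calibration chain to
    carry ultrasound pixels into MR space).
    """

    transform: RigidTransform
    mse_trace: np.ndarray
    iterations: int
    converged: bool
    stop_reason: str

    @property
    def tracker_to_mr(self) -> RigidTransform:
        return self.transform.invert()

    def to_dict(self) -> dict:
        return {
            "matrix": self.transform.matrix.tolist(),
            "units": "mm",
            "mse_trace": np.asarray(self.mse_trace).tolist(),
            "iterations": self.iterations,
            "converged": self.converged,
            "stop_reason": self.stop_reason,
        }


# ---------------------------------------------------------------------------
# Procrustes initialization
# ---------------------------------------------------------------------------


def _weighted_rigid_fit(
    source: np.ndarray, targets: np.ndarray, weights: np.ndarray
) -> RigidTransform:
    """Closed-form weighted least-squares rigid fit (SVD / Kabsch), det +1."""
    w = weights / weights.sum()
    cs = w @ source
    ct = w @ targets
    H = (source - cs).T @ ((targets - ct) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, ct - R @ cs)


def procrustes_init(
    mr_landmarks: np.ndarray, us_landmarks: np.ndarray
) -> RigidTransform:
    """Least-squares rigid alignment of three paired anatomical landmarks.

    The landmark triples are picked at the cranial end, the caudal end and
    the kidney hilum, in the MR segmentation and in the ultrasound slices.
    No scaling is estimated; the rotation has determinant +1.
    """
    src = np.asarray(mr_landmarks, dtype=float).reshape(-1, 3)
    tgt = np.asarray(us_landmarks, dtype=float).reshape(-1, 3)
    if src.shape != (3, 3) or tgt.shape != (3, 3):
        raise DegeneracyError("exactly three landmark correspondences required")
    for pts, name in ((src, "MR"), (tgt, "US")):
        span = np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        scale = max(np.ptp(pts), 1.0)
        if span < 1e-9 * scale**2:
            raise DegeneracyError(f"{name} landmarks are collinear or duplicated")
    return _weighted_rigid_fit(src, tgt, np.ones(3))


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def _closest_distances(
    points_mr: np.ndarray, mesh: SurfaceModel
) -> tuple[np.ndarray, np.ndarray]:
    hits = closest_points_on_surface(points_mr, mesh)
    return (
        np.asarray([h.point for h in hits]),
        np.asarray([h.distance for h in hits]),
    )


def oicp_objective(
    T: RigidTransform,
    features: FeaturePointSet,
    kidney: SurfaceModel,
    vessels: SurfaceModel | None = None,
) -> float:
    """Categorized mean squared closest-point distance, in mm².

    ``T`` maps the tracker-space features into MR space (i.e. T = T_R⁻¹ for
    a registration result T_R). Each category contributes the mean of its
    squared surface distances; the vessel term is dropped when there are no
    vessel points.
    """
    if len(kidney) == 0:
        raise GeometryError("empty kidney mesh")
    _, dk = _closest_distances(T.apply(features.kidney_points), kidney)
    mse = float(np.mean(dk**2))
    if features.v2:
        if vessels is None or len(vessels) == 0:
            raise GeometryError("vessel points given but vessel mesh is empty")
        _, dv = _closest_distances(T.apply(features.vessel_points), vessels)
        mse += float(np.mean(dv**2))
    return mse


# ---------------------------------------------------------------------------
# Constrained rigid update
# ---------------------------------------------------------------------------


def _offset_params(T: RigidTransform, T_0: RigidTransform) -> tuple[np.ndarray, np.ndarray]:
    D = T.relative_to(T_0)
    return Rotation.from_matrix(D.rotation).as_rotvec(), D.translation


def _from_offset_params(r: np.ndarray, u: np.ndarray, T_0: RigidTransform) -> RigidTransform:
    D = RigidTransform(Rotation.from_rotvec(r).as_matrix(), u)
    return D.compose(T_0)


def _project_to_bounds(
    T: RigidTransform, T_0: RigidTransform, cfg: OICPConfig
) -> RigidTransform:
    r, u = _offset_params(T, T_0)
    alpha_rad = np.deg2rad(cfg.alpha)
    if np.linalg.norm(r) > alpha_rad:
        r = r * (alpha_rad / np.linalg.norm(r))
    if np.linalg.norm(u) > cfg.A:
        u = u * (cfg.A / np.linalg.norm(u))
    return _from_offset_params(r, u, T_0)


def _is_feasible(T: RigidTransform, T_0: RigidTransform, cfg: OICPConfig, slack: float = 1e-9) -> bool:
    r, u = _offset_params(T, T_0)
    return (
        np.linalg.norm(r) <= np.deg2rad(cfg.alpha) + slack
        and np.linalg.norm(u) <= cfg.A + slack
    )


def _corr_mse(T: RigidTransform, source: np.ndarray, targets: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * np.sum((T.apply(source) - targets) ** 2, axis=1)))


def rigid_update_constrained(
    source: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray | None,
    T_prev: RigidTransform,
    T_0: RigidTransform,
    cfg: OICPConfig,
) -> RigidTransform:
    """One bounded rigid update of the ICP: minimize the weighted mean squared
    correspondence distance over the feasible set around T_0.

    The closed-form weighted rigid fit is taken when it already satisfies the
    bounds. Otherwise it is projected onto the feasible set (axis-angle
    rescaled to alpha, translation offset clipped to A) and refined by a
    bounded local search; the best feasible candidate is returned only if it
    does not increase the objective relative to ``T_prev``, which keeps the
    iteration monotone.
    """
    source = np.asarray(source, dtype=float).reshape(-1, 3)
    targets = np.asarray(targets, dtype=float).reshape(-1, 3)
    if len(source) < 3 or len(source) != len(targets):
        raise DegeneracyError("at least 3 paired correspondences required")
    if np.ptp(source, axis=0).max() < 1e-9:
        raise DegeneracyError("degenerate correspondences: all source points identical")
    w = np.ones(len(source)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()

    best = T_prev
    best_mse = _corr_mse(T_prev, source, targets, w)

    T_fit = _weighted_rigid_fit(source, targets, w)
    candidates = []
    if _is_feasible(T_fit, T_0, cfg):
        candidates.append(T_fit)
    else:
        proj = _project_to_bounds(T_fit, T_0, cfg)
        candidates.append(proj)
        candidates.append(_refine_bounded(proj, source, targets, w, T_0, cfg))

    for cand in candidates:
        if not _is_feasible(cand, T_0, cfg):
            continue
        mse = _corr_mse(cand, source, targets, w)
        if mse < best_mse - 1e-15:
            best, best_mse = cand, mse
    return best


def _refine_bounded(
    T_start: RigidTransform,
    source: np.ndarray,
    targets: np.ndarray,
    w: np.ndarray,
    T_0: RigidTransform,
    cfg: OICPConfig,
) -> RigidTransform:
    """Local SLSQP pass over the 6 offset parameters within the bounds."""
    alpha_rad = np.deg2rad(cfg.alpha)
    r0, u0 = _offset_params(T_start, T_0)
    x0 = np.concatenate([r0, u0])

    def f(x):
        return _corr_mse(_from_offset_params(x[:3], x[3:], T_0), source, targets, w)

    cons = (
        {"type": "ineq", "fun": lambda x: alpha_rad**2 - x[:3] @ x[:3]},
        {"type": "ineq", "fun": lambda x: cfg.A**2 - x[3:] @ x[3:]},
    )
    res = minimize(f, x0, method="SLSQP", constraints=cons, options={"maxiter": 60})
    T = _from_offset_params(res.x[:3], res.x[3:], T_0)
    if not _is_feasible(T, T_0, cfg):
        T = _project_to_bounds(T, T_0, cfg)
    return T


# ---------------------------------------------------------------------------
# OICP driver
# ---------------------------------------------------------------------------


def oicp_register(
    features: FeaturePointSet,
    kidney: SurfaceModel,
    vessels: SurfaceModel | None,
    T_0: RigidTransform,
    cfg: OICPConfig | None = None,
) -> RegistrationResult:
    """Orthogonal-slice constrained ICP.

    Alternates (1) closest-point correspondence: features are carried into MR
    space with the current T_R⁻¹ and matched to the closest points on their
    category's surface, and (2) a bounded rigid update fitted on those
    correspondences in the MR→tracker direction. Iteration stops when the
    MSE decrease falls below ``cfg.h`` (mm²) or after ``cfg.n_max`` updates.
    """
    cfg = cfg or OICPConfig()
    if len(kidney) == 0:
        raise GeometryError("empty kidney mesh")
    if features.v2 and (vessels is None or len(vessels) == 0):
        raise GeometryError("vessel points given but vessel mesh is empty")

    pts_tracker, w = features.stacked()
    T = T_0
    mse_trace: list[float] = []
    stop_reason = "max_iterations"
    converged = False

    def correspondences(T_cur: RigidTransform) -> tuple[np.ndarray, float]:
        inv = T_cur.invert()
        ck, dk = _closest_distances(inv.apply(features.kidney_points), kidney)
        mse = float(np.mean(dk**2))
        targets_mr = [ck]
        if features.v2:
            cv, dv = _closest_distances(inv.apply(features.vessel_points), vessels)
            mse += float(np.mean(dv**2))
            targets_mr.append(cv)
        return np.vstack(targets_mr), mse

    source_mr, mse = correspondences(T)
    mse_trace.append(mse)
    logger.debug("OICP iter 0: mse=%.6f mm^2", mse)

    for n in range(1, cfg.n_max + 1):
        T = rigid_update_constrained(source_mr, pts_tracker, w, T, T_0, cfg)
        # objective(T_new) <= correspondence MSE of T_new <= objective(T_prev),
        # so the trace is non-increasing without any clamping
        source_mr, mse = correspondences(T)
        mse_trace.append(mse)
        logger.debug("OICP iter %d: mse=%.6f mm^2", n, mse_trace[-1])
        if mse_trace[-2] - mse_trace[-1] < cfg.h:
            stop_reason = "mse_threshold"
            converged = True
            break

    iterations = len(mse_trace) - 1
    logger.info(
        "OICP finished: %d iterations, mse %.4f -> %.4f mm^2 (%s)",
        iterations,
        mse_trace[0],
        mse_trace[-1],
        stop_reason,
    )
    return RegistrationResult(
        transform=T,
        mse_trace=np.asarray(mse_trace),
        iterations=iterations,
        converged=converged,
        stop_reason=stop_reason,
    )
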