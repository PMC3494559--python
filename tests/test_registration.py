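import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from renalnav.geometry import RigidTransform, closest_point_on_surface
from renalnav.registration import (
    DegeneracyError,
    FeaturePointSet,
    OICPConfig,
    oicp_objective,
    oicp_register,
    procrustes_init,
    rigid_update_constrained,
)
from renalnav.synthetic import SceneSpec, generate_scene
from renalnav.evaluation import register_scene, rms_tre

from conftest import brute_force_closest


@pytest.fixture(scope="module")
def clean_scene():
    return generate_scene(
        SceneSpec(
            truth_translation=(6.0, -4.0, 8.0),
            truth_rotation_axis=(1.0, 0.5, -0.2),
            truth_rotation_deg=9.0,
            point_noise_sd=0.0,
            landmark_noise_sd=0.0,
            seed=77,
        )
    )


class TestProcrustes:
    def test_identical_triples_give_identity(self):
        pts = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0]])
        T = procrustes_init(pts, pts)
        assert T.almost_equal(RigidTransform.identity(), atol=1e-12)

    def test_exact_recovery_of_rigid_transform(self, rng):
        for _ in range(100):
            T_true = RigidTransform.random(rng)
            src = rng.uniform(-50, 50, (3, 3))
            while np.linalg.norm(np.cross(src[1] - src[0], src[2] - src[0])) < 1.0:
                src = rng.uniform(-50, 50, (3, 3))
            T = procrustes_init(src, T_true.apply(src))
            assert T.almost_equal(T_true, atol=1e-9)

    def test_collinear_landmarks_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        tgt = np.array([[0.0, 0, 0], [0, 1, 0], [1, 1, 0]])
        with pytest.raises(DegeneracyError):
            procrustes_init(line, tgt)

    def test_noisy_fit_beats_rotation_grid_oracle(self, rng):
        """The SVD solution is the least-squares optimum: no rotation on a
        coarse Euler grid (with its optimal translation) does better."""
        src = rng.uniform(-30, 30, (3, 3))
        tgt = RigidTransform.random(rng).apply(src) + rng.normal(0, 2.0, (3, 3))
        T = procrustes_init(src, tgt)
        best = np.sum((T.apply(src) - tgt) ** 2)
        angles = np.linspace(-np.pi, np.pi, 13)
        for a in angles:
            for b in np.linspace(-np.pi / 2, np.pi / 2, 7):
                for c in angles:
                    R = Rotation.from_euler("zyx", [a, b, c]).as_matrix()
                    t = tgt.mean(axis=0) - R @ src.mean(axis=0)  # optimal translation
                    cost = np.sum((src @ R.T + t - tgt) ** 2)
                    assert best <= cost + 1e-9


class TestObjective:
    def test_exactly_aligned_features_give_zero(self, clean_scene):
        T = clean_scene.truth.invert()  # tracker -> MR
        mse = oicp_objective(T, clean_scene.features, clean_scene.kidney, clean_scene.vessels)
        assert mse == pytest.approx(0.0, abs=1e-12)

    def test_single_point_mean_is_squared_distance(self, icosphere):
        p = np.array([0.0, 0.0, 2.0])
        d = closest_point_on_surface(p, icosphere).distance
        feats = FeaturePointSet(np.array([p, p, p]))
        mse = oicp_objective(RigidTransform.identity(), feats, icosphere)
        assert mse == pytest.approx(d**2, rel=1e-12)

    def test_matches_naive_oracle(self, clean_scene, rng):
        T = RigidTransform.random(rng, max_translation=10.0).compose(
            clean_scene.truth.invert()
        )
        feats = FeaturePointSet(
            clean_scene.features.kidney_points[:6],
            clean_scene.features.vessel_points[:4],
        )
        mse = oicp_objective(T, feats, clean_scene.kidney, clean_scene.vessels)
        dk = [
            brute_force_closest(q, clean_scene.kidney)[1]
            for q in T.apply(feats.kidney_points)
        ]
        dv = [
            brute_force_closest(q, clean_scene.vessels)[1]
            for q in T.apply(feats.vessel_points)
        ]
        naive = np.mean(np.square(dk)) + np.mean(np.square(dv))
        assert mse == pytest.approx(naive, rel=1e-9)

    def test_vessel_points_without_mesh_rejected(self, clean_scene):
        with pytest.raises(Exception):
            oicp_objective(
                RigidTransform.identity(), clean_scene.features, clean_scene.kidney, None
            )


class TestConstrainedUpdate:
    def test_targets_equal_source_keeps_previous(self, rng):
        src = rng.uniform(-20, 20, (10, 3))
        T_prev = RigidTransform.identity()
        T = rigid_update_constrained(src, src, None, T_prev, T_prev, OICPConfig())
        assert T.almost_equal(T_prev, atol=1e-12)

    def test_unconstrained_optimum_within_bounds(self, rng):
        """When the closed-form fit is feasible it is returned exactly."""
        src = rng.uniform(-30, 30, (12, 3))
        T_true = RigidTransform.from_axis_angle([0, 1, 0], 12.0, [5, -3, 8])
        tgt = T_true.apply(src)
        T = rigid_update_constrained(
            src, tgt, None, RigidTransform.identity(), RigidTransform.identity(), OICPConfig()
        )
        assert T.almost_equal(T_true, atol=1e-9)

    def test_out_of_bounds_projected_beats_grid(self, rng):
        """With the optimum outside the bounds the result is feasible and at
        least as good as every transform on a translation x rotation grid
        inside the feasible region."""
        cfg = OICPConfig(A=10.0, alpha=10.0)
        src = rng.uniform(-30, 30, (15, 3))
        T_true = RigidTransform.from_axis_angle([0, 0, 1], 25.0, [20.0, 5.0, -3.0])
        tgt = T_true.apply(src)
        T_0 = RigidTransform.identity()
        T = rigid_update_constrained(src, tgt, None, T_0, T_0, cfg)
        D = T.relative_to(T_0)
        assert np.linalg.norm(D.translation) <= cfg.A + 1e-9
        assert D.rotation_angle_deg <= cfg.alpha + 1e-9
        mse = np.mean(np.sum((T.apply(src) - tgt) ** 2, axis=1))
        axis = np.array([0.0, 0.0, 1.0])
        for ang in np.linspace(-cfg.alpha, cfg.alpha, 30):
            R = Rotation.from_rotvec(np.deg2rad(ang) * axis).as_matrix()
            for tx in np.linspace(-cfg.A, cfg.A, 10):
                for ty in np.linspace(-cfg.A, cfg.A, 10):
                    for tz in np.linspace(-cfg.A, cfg.A, 10):
                        t = np.array([tx, ty, tz])
                        if np.linalg.norm(t) > cfg.A:
                            continue
                        cand = np.mean(
                            np.sum((src @ R.T + t - tgt) ** 2, axis=1)
                        )
                        assert mse <= cand + 1e-9

    def test_too_few_correspondences_rejected(self):
        with pytest.raises(DegeneracyError):
            rigid_update_constrained(
                np.zeros((2, 3)),
                np.zeros((2, 3)),
                None,
                RigidTransform.identity(),
                RigidTransform.identity(),
                OICPConfig(),
            )

    def test_identical_sources_rejected(self):
        with pytest.raises(DegeneracyError):
            rigid_update_constrained(
                np.ones((5, 3)),
                np.random.default_rng(0).uniform(size=(5, 3)),
                None,
                RigidTransform.identity(),
                RigidTransform.identity(),
                OICPConfig(),
            )


class TestOICP:
    def test_already_aligned_returns_t0_one_iteration(self, clean_scene):
        T_0 = clean_scene.truth
        res = oicp_register(
            clean_scene.features, clean_scene.kidney, clean_scene.vessels, T_0
        )
        assert res.iterations == 1
        assert res.stop_reason == "mse_threshold"
        assert res.converged
        assert res.transform.almost_equal(T_0, atol=1e-9)
        assert res.mse_trace[0] == pytest.approx(0.0, abs=1e-12)

    def test_displaced_init_recovers_truth(self, clean_scene):
        """From an initialization 10 mm / 10 deg off the truth, the
        constrained ICP on exact surface points recovers the ground truth to
        sub-half-millimetre TRE."""
        D = RigidTransform.from_axis_angle([0.3, 0.5, 1.0], 10.0, [6.0, -6.0, 5.3])
        T_0 = D.compose(clean_scene.truth)
        res = oicp_register(
            clean_scene.features,
            clean_scene.kidney,
            clean_scene.vessels,
            T_0,
            OICPConfig(h=1e-10, n_max=500),
        )
        tre = rms_tre(res.transform, clean_scene.truth, clean_scene.kidney.vertices)
        assert tre < 0.5

    def test_translation_beyond_bound_clamps_to_boundary(self, clean_scene):
        """A 30 mm true residual translation lands on the A = 28 mm
        constraint boundary."""
        D = RigidTransform(np.eye(3), np.array([30.0, 0.0, 0.0]))
        T_0 = D.invert().compose(clean_scene.truth)
        res = oicp_register(
            clean_scene.features,
            clean_scene.kidney,
            clean_scene.vessels,
            T_0,
            OICPConfig(h=1e-9, n_max=300),
        )
        off = res.transform.relative_to(T_0)
        assert np.linalg.norm(off.translation) == pytest.approx(28.0, abs=1e-6)

    def test_mse_trace_monotone_and_constraints_hold(self):
        cfg = OICPConfig()
        for seed in range(8):
            scene = generate_scene(SceneSpec.with_random_motion(seed, motion_scale=0.9))
            res = register_scene(scene, cfg)
            assert np.all(np.diff(res.mse_trace) <= 1e-12)
            T_0 = procrustes_init(scene.mr_landmarks, scene.us_landmarks)
            off = res.transform.relative_to(T_0)
            assert off.rotation_angle_deg <= cfg.alpha + 1e-9
            assert np.linalg.norm(off.translation) <= cfg.A + 1e-9

    def test_result_serialization_fields(self, clean_scene, tmp_path):
        from renalnav import io

        res = register_scene(clean_scene)
        io.write_result_json(tmp_path / "r.json", res)
        T = io.read_result_transform(tmp_path / "r.json")
        assert T.almost_equal(res.transform, atol=1e-12)
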