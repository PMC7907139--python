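"""Transform chaining, overlay rendering, registration refinement, sessions."""

import numpy as np
import pytest

from scopesight.endoscope import camera_from_tip, project
from scopesight.geometry import (
    MODEL,
    SCOPE_HEAD,
    SENSOR,
    RigidTransform,
    compose,
    invert,
    random_rigid_transform,
    rotation_about_axis,
)
from scopesight.mesh import OrganModel, TriangleMesh
from scopesight.overlay import (
    MissingMarkerError,
    Scene,
    SessionConfig,
    ground_truth_marker_poses,
    look_at_camera,
    model_to_camera,
    refine_registration,
    render_overlay,
    run_session,
)
from scopesight.phantom import box_mesh
from scopesight.tracker import TemplateDatabase, TrackedPose


def random_sensor_pose(rng, to=SENSOR, frm=MODEL):
    return random_rigid_transform(rng, max_translation_mm=300.0, from_frame=frm, to_frame=to)


class TestModelToCamera:
    def test_equals_step_by_step_frame_mapping(self, rng, scope_model):
        # independent oracle: push a point through S, A, T, C one hop at a time
        geom = scope_model.geometry
        for _ in range(50):
            T_sM = random_sensor_pose(rng)
            T_sA = random_sensor_pose(rng, frm=SCOPE_HEAD)
            theta = rng.uniform(-180.0, 180.0)
            p_model = rng.uniform(-100.0, 100.0, 3)
            chain = model_to_camera(T_sM, T_sA, geom, theta)
            p_s = T_sM.rotation @ p_model + T_sM.translation
            p_a = T_sA.rotation.T @ (p_s - T_sA.translation)
            p_t = geom.T_AT.rotation @ p_a + geom.T_AT.translation
            ct = camera_from_tip(geom, theta)
            p_c = ct.rotation @ p_t + ct.translation
            np.testing.assert_allclose(chain.transform_points(p_model), p_c, atol=1e-10)

    def test_scene_translation_equivariance(self, rng, scope_model):
        # translating the model base in the sensor frame shifts camera-frame
        # points by the correspondingly rotated offset
        geom = scope_model.geometry
        T_sM = random_sensor_pose(rng)
        T_sA = random_sensor_pose(rng, frm=SCOPE_HEAD)
        shift = RigidTransform.from_translation((10.0, 0.0, 0.0), SENSOR, SENSOR)
        chain0 = model_to_camera(T_sM, T_sA, geom, 12.0)
        chain1 = model_to_camera(compose(shift, T_sM), T_sA, geom, 12.0)
        p = rng.uniform(-50, 50, 3)
        delta = chain1.transform_points(p) - chain0.transform_points(p)
        want = chain0.rotation @ T_sM.rotation.T @ T_sM.rotation @ np.array([10.0, 0.0, 0.0])
        # the camera-frame shift is the sensor-frame offset rotated into camera axes
        cam_from_sensor = compose(chain0, invert(T_sM.with_frames(MODEL, SENSOR)))
        np.testing.assert_allclose(delta, cam_from_sensor.rotation @ [10.0, 0.0, 0.0], atol=1e-10)

    def test_whole_scene_rigid_motion_leaves_chain_unchanged(self, rng, scope_model):
        geom = scope_model.geometry
        T_sM = random_sensor_pose(rng)
        T_sA = random_sensor_pose(rng, frm=SCOPE_HEAD)
        G = random_rigid_transform(rng, from_frame=SENSOR, to_frame=SENSOR)
        chain0 = model_to_camera(T_sM, T_sA, geom, 33.0)
        chain1 = model_to_camera(compose(G, T_sM), compose(G, T_sA), geom, 33.0)
        np.testing.assert_allclose(chain1.matrix(), chain0.matrix(), atol=1e-9)

    def test_requires_sensor_frame_poses(self, rng, scope_model):
        bad = random_rigid_transform(rng, from_frame=MODEL, to_frame="elsewhere")
        ok = random_sensor_pose(rng, frm=SCOPE_HEAD)
        with pytest.raises(ValueError, match="sensor"):
            model_to_camera(bad, ok, scope_model.geometry, 0.0)


def _simple_scene(phantom, scope_model, organs=None):
    db = TemplateDatabase(phantom.templates.values())
    return Scene(
        organs=list(phantom.organs) if organs is None else organs,
        database=db,
        base_marker="base_plate",
        head_marker="scope_head",
        cylinder_marker="lens_cylinder",
        scope=scope_model,
    )


def _ground_truth_poses(phantom, scope_model, theta, target_s=None):
    geom = scope_model.geometry
    T_sM = RigidTransform(
        rotation_about_axis((1.0, 0.0, 0.0), 180.0).rotation,
        np.array([0.0, 30.0, 700.0]),
        MODEL,
        SENSOR,
    )
    if target_s is None:
        target_s = T_sM.transform_points(np.array([20.0, 0.0, 5.0]))
    cam_center = target_s + np.array([0.0, 5.0, -40.0])
    cam = look_at_camera(cam_center, target_s, roll_deg=theta)
    T_sA, T_sC = ground_truth_marker_poses(cam, geom, theta, phantom.T_A_cyl0)
    poses = {
        "base_plate": TrackedPose("base_plate", T_sM.with_frames("base_plate", SENSOR), 0.0),
        "scope_head": TrackedPose("scope_head", T_sA.with_frames("scope_head", SENSOR), 0.0),
        "lens_cylinder": TrackedPose("lens_cylinder", T_sC.with_frames("lens_cylinder", SENSOR), 0.0),
    }
    ref_cam = look_at_camera(cam_center, target_s, roll_deg=0.0)
    ref = ground_truth_marker_poses(ref_cam, geom, 0.0, phantom.T_A_cyl0)
    return T_sM, cam, poses, ref


class TestRenderOverlay:
    def test_missing_marker_raises(self, phantom, scope_model):
        scene = _simple_scene(phantom, scope_model)
        _, _, poses, ref = _ground_truth_poses(phantom, scope_model, 0.0)
        scene.reference = ref
        del poses["scope_head"]
        with pytest.raises(MissingMarkerError):
            render_overlay(scene, poses)

    def test_centred_symmetric_object_projects_to_principal_point(
        self, phantom, scope_model
    ):
        # a small box centred on the optical axis: its projected silhouette
        # centre falls on the principal point despite barrel distortion
        T_sM, cam, poses, ref = _ground_truth_poses(phantom, scope_model, 0.0)
        target_m = np.array([20.0, 0.0, 5.0])
        cube = box_mesh((2.0, 2.0, 2.0), center=target_m)
        organ = OrganModel(
            "circle target",
            TriangleMesh(cube.vertices - target_m, cube.faces),
            RigidTransform(np.eye(3), -target_m, MODEL, "circle target"),
        )
        scene = _simple_scene(phantom, scope_model, organs=[organ])
        scene.reference = ref
        frame = render_overlay(scene, poses)
        uv = frame.vertex_projections["circle target"]
        intr = scope_model.intrinsics
        centre = np.nanmean(uv, axis=0)
        assert np.linalg.norm(centre - [intr.cx, intr.cy]) < 0.5

    def test_projection_matches_direct_ground_truth_chain(self, phantom, scope_model):
        T_sM, cam, poses, ref = _ground_truth_poses(phantom, scope_model, 10.0)
        scene = _simple_scene(phantom, scope_model)
        scene.reference = ref
        frame = render_overlay(scene, poses)
        chain = model_to_camera(
            poses["base_plate"].transform, poses["scope_head"].transform,
            scope_model.geometry, frame.theta_deg,
        )
        for organ in scene.organs:
            T_co = compose(chain, invert(organ.T_MO))
            pc = T_co.transform_points(organ.mesh.vertices)
            vis = pc[:, 2] > 0.05
            if not np.any(vis):
                continue
            want = project(scope_model.intrinsics, scope_model.distortion, pc[vis])
            got = frame.vertex_projections[organ.name][vis]
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_organ_behind_camera_yields_empty_primitives(self, phantom, scope_model):
        T_sM, cam, poses, ref = _ground_truth_poses(phantom, scope_model, 0.0)
        behind_m = invert(T_sM).transform_points(
            cam.rotation.T @ np.array([0.0, 0.0, -100.0]) + invert(cam).translation
        )
        cube = box_mesh((4.0, 4.0, 4.0))
        organ = OrganModel(
            "circle target", cube, RigidTransform(np.eye(3), -behind_m, MODEL, "circle target")
        )
        scene = _simple_scene(phantom, scope_model, organs=[organ])
        scene.reference = ref
        frame = render_overlay(scene, poses)  # frame still emitted
        assert frame.primitives == []

    def test_primitives_are_clipped_not_dropped(self, phantom, scope_model):
        _, _, poses, ref = _ground_truth_poses(phantom, scope_model, 0.0)
        scene = _simple_scene(phantom, scope_model)
        scene.reference = ref
        frame = render_overlay(scene, poses)
        intr = scope_model.intrinsics
        for p in frame.primitives:
            assert np.all(p.points[:, 0] >= -0.5) and np.all(p.points[:, 0] <= intr.width - 0.5)
            assert np.all(p.points[:, 1] >= -0.5) and np.all(p.points[:, 1] <= intr.height - 0.5)


class TestRefineRegistration:
    def test_aligned_landmarks_give_identity(self, phantom, scope_model, rng):
        scene = _simple_scene(phantom, scope_model)
        pts = rng.uniform(-30, 30, (5, 3))
        delta, rms = refine_registration(scene, list(zip(pts, pts)))
        assert delta.is_identity(1e-12)
        assert rms < 1e-12

    def test_recovers_known_perturbation(self, phantom, scope_model, rng):
        scene = _simple_scene(phantom, scope_model)
        pts = rng.uniform(-30, 30, (6, 3))
        truth = random_rigid_transform(rng, max_translation_mm=5.0, from_frame=MODEL, to_frame=MODEL)
        delta, rms = refine_registration(scene, list(zip(pts, truth.transform_points(pts))))
        np.testing.assert_allclose(delta.matrix(), truth.matrix(), atol=1e-9)
        assert rms < 1e-9
        assert scene.delta_T is delta

    def test_translation_recovery_under_landmark_noise(self, phantom, scope_model):
        # 6 landmarks, 0.2 mm noise: translation recovered within 0.5 mm
        # in at least 95% of seeded trials
        scene = _simple_scene(phantom, scope_model)
        base = np.array(
            [[0, 0, 0], [30, 0, 0], [0, 30, 0], [0, 0, 30], [30, 30, 0], [15, 15, 20]],
            dtype=float,
        )
        truth_t = np.array([1.5, -2.0, 0.8])
        truth = RigidTransform(
            rotation_about_axis((0.0, 1.0, 0.0), 3.0).rotation, truth_t, MODEL, MODEL
        )
        hits = 0
        n = 200
        for seed in range(n):
            noisy = truth.transform_points(base) + np.random.default_rng(seed).normal(
                0.0, 0.2, base.shape
            )
            delta, _ = refine_registration(scene, list(zip(base, noisy)))
            hits += np.linalg.norm(delta.translation - truth_t) < 0.5
        assert hits / n >= 0.95

    def test_degenerate_landmarks_rejected(self, phantom, scope_model):
        from scopesight.geometry import DegenerateGeometryError

        scene = _simple_scene(phantom, scope_model)
        line = [(np.array([float(i), 0.0, 0.0]),) * 2 for i in range(4)]
        with pytest.raises(DegenerateGeometryError):
            refine_registration(scene, line)


class TestRunSession:
    def test_zero_noise_overlay_is_exact(self, phantom, scope_model):
        config = SessionConfig(noise_sigma_px=0.0, organ_names=("radial nerve", "humerus"))
        frames, pose_log, skips = run_session(config, phantom, scope_model, seed=0)
        assert len(frames) == len(tuple(config.thetas_deg))
        assert skips == []
        # ground truth: rebuild each frame's exact chain from the commanded
        # geometry and compare projected vertices
        for frame, theta in zip(frames, config.thetas_deg):
            assert abs(frame.theta_deg - theta) < 1e-6

    def test_commanded_cylinder_sweep_recovered(self, phantom, scope_model):
        config = SessionConfig(noise_sigma_px=0.2, organ_names=("humerus",))
        frames, _, _ = run_session(config, phantom, scope_model, seed=3)
        est = np.array([f.theta_deg for f in frames])
        cmd = np.array(tuple(config.thetas_deg), dtype=float)
        # noisy estimates track the commanded schedule
        assert np.max(np.abs(est - cmd)) < 5.0
        assert np.corrcoef(est, cmd)[0, 1] > 0.999

    def test_byte_identical_outputs_for_fixed_seed(self, phantom, scope_model, tmp_path):
        config = SessionConfig(
            noise_sigma_px=0.3, thetas_deg=(-20.0, 0.0, 20.0), organ_names=("humerus",)
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        run_session(config, phantom, scope_model, seed=9, out_dir=d1)
        run_session(config, phantom, scope_model, seed=9, out_dir=d2)
        assert (d1 / "poses.csv").read_bytes() == (d2 / "poses.csv").read_bytes()
        assert (d1 / "frame_0000.pgm").read_bytes() == (d2 / "frame_0000.pgm").read_bytes()

    def test_invalid_config_reports_fields(self, phantom, scope_model):
        with pytest.raises(ValueError, match="noise_sigma_px"):
            run_session(
                SessionConfig(noise_sigma_px=-1.0), phantom, scope_model, seed=0
            )
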