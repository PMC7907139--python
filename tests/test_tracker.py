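"""Simulated stereo tracker: triangulation, pose fits, template identity."""

import numpy as np
import pytest

from scopesight.geometry import SENSOR, RigidTransform, rotation_geodesic_deg
from scopesight.tracker import (
    DegenerateTriangulationError,
    MarkerTemplate,
    NoMatchError,
    TemplateDatabase,
    VisibilityError,
    add_template,
    default_rig,
    estimate_pose,
    identify_template,
    observe_marker,
    triangulate,
    _project_to_camera,
)


SQUARE5 = np.array(
    [[0.0, 0.0, 0.0], [40.0, 0.0, 0.0], [40.0, 40.0, 0.0], [0.0, 40.0, 0.0], [20.0, 20.0, 12.0]]
)


def marker(name="m", pts=SQUARE5):
    return MarkerTemplate(name, pts)


def pose_at(z=600.0, name="m"):
    return RigidTransform(np.eye(3), np.array([-20.0, -20.0, z]), name, SENSOR)


class TestMarkerTemplate:
    def test_needs_four_points(self):
        with pytest.raises(ValueError, match=">= 4"):
            MarkerTemplate("t", SQUARE5[:3])

    def test_rejects_close_points(self):
        pts = SQUARE5.copy()
        pts[1] = pts[0] + [0.5, 0.0, 0.0]
        with pytest.raises(ValueError, match="1 mm"):
            MarkerTemplate("t", pts)

    def test_rejects_collinear(self):
        line = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [20.0, 0.0, 0.0], [30.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="collinear"):
            MarkerTemplate("t", line)


class TestTriangulate:
    def test_roundtrip_zero_noise(self, rig):
        p = np.array([15.0, -25.0, 550.0])
        lp = _project_to_camera(rig.left, rig.left_pose, p)
        rp = _project_to_camera(rig.right, rig.right_pose, p)
        np.testing.assert_allclose(triangulate(rig, lp, rp), p, atol=1e-9)

    def test_midplane_symmetry(self, rig):
        # a point on the baseline midplane (x = 0) reconstructs with x = 0
        p = np.array([0.0, 12.0, 500.0])
        lp = _project_to_camera(rig.left, rig.left_pose, p)
        rp = _project_to_camera(rig.right, rig.right_pose, p)
        assert abs(triangulate(rig, lp, rp)[0]) < 1e-9

    def test_near_parallel_rays_raise(self):
        rig = default_rig(convergence_deg=0.0)
        centre = np.array([rig.left.cx, rig.left.cy])
        with pytest.raises(DegenerateTriangulationError):
            triangulate(rig, centre, centre)

    def test_out_of_bounds_pixel_rejected(self, rig):
        with pytest.raises(ValueError, match="outside image bounds"):
            triangulate(rig, np.array([-10.0, 10.0]), np.array([10.0, 10.0]))

    def test_error_shrinks_with_longer_baseline(self):
        # Monte-Carlo: doubling the baseline improves depth triangulation
        rigs = {b: default_rig(baseline_mm=b) for b in (120.0, 240.0)}
        errs = {b: [] for b in rigs}
        rng = np.random.default_rng(11)
        for _ in range(400):
            p = np.array([rng.uniform(-40, 40), rng.uniform(-40, 40), rng.uniform(450, 650)])
            for b, rg in rigs.items():
                lp = _project_to_camera(rg.left, rg.left_pose, p)
                rp = _project_to_camera(rg.right, rg.right_pose, p)
                noise = rng.normal(0.0, 0.1, 4)
                q = triangulate(rg, lp + noise[:2], rp + noise[2:])
                errs[b].append(np.linalg.norm(q - p))
        assert np.median(errs[240.0]) < np.median(errs[120.0])


class TestObserveMarker:
    def test_zero_noise_recovers_transformed_points(self, rig):
        t = pose_at()
        obs = observe_marker(rig, marker(), t, 0.0)
        np.testing.assert_allclose(obs.points, t.transform_points(SQUARE5), atol=1e-9)
        assert obs.frame == SENSOR

    def test_deterministic_under_seed(self, rig):
        a = observe_marker(rig, marker(), pose_at(), 0.5, seed=7)
        b = observe_marker(rig, marker(), pose_at(), 0.5, seed=7)
        np.testing.assert_array_equal(a.points, b.points)

    def test_noise_requires_seed(self, rig):
        with pytest.raises(ValueError, match="seed"):
            observe_marker(rig, marker(), pose_at(), 0.5)

    def test_point_behind_camera_raises(self, rig):
        behind = RigidTransform(np.eye(3), np.array([0.0, 0.0, -500.0]), "m", SENSOR)
        with pytest.raises(VisibilityError, match=r"\[0, 1, 2, 3, 4\]"):
            observe_marker(rig, marker(), behind, 0.0)

    def test_3d_error_scales_linearly_with_pixel_noise(self, rig):
        # slope check over sigma in {0.1, 0.2, 0.5}: medians near-proportional
        true = pose_at()
        ideal = true.transform_points(SQUARE5)
        med = {}
        for sigma in (0.1, 0.2, 0.5):
            errs = []
            for seed in range(150):
                obs = observe_marker(rig, marker(), true, sigma, seed=seed)
                errs.append(np.linalg.norm(obs.points - ideal, axis=1).mean())
            med[sigma] = np.median(errs)
        assert 1.6 < med[0.2] / med[0.1] < 2.5
        assert 3.5 < med[0.5] / med[0.1] < 6.5


class TestEstimatePose:
    def test_noise_free_recovery(self, rig):
        true = pose_at()
        obs = observe_marker(rig, marker(), true, 0.0)
        est = estimate_pose(marker(), obs)
        assert est.rms_residual_mm < 1e-8
        np.testing.assert_allclose(est.transform.matrix(), true.matrix(), atol=1e-8)

    def test_planar_template_not_degenerate(self, rig):
        planar = MarkerTemplate("p", SQUARE5[:4])
        true = pose_at(name="p")
        est = estimate_pose(planar, observe_marker(rig, planar, true, 0.0))
        np.testing.assert_allclose(est.transform.matrix(), true.matrix(), atol=1e-8)

    def test_count_mismatch_rejected(self, rig):
        obs = observe_marker(rig, marker(), pose_at(), 0.0)
        from scopesight.geometry import PointSet

        with pytest.raises(ValueError, match="points"):
            estimate_pose(marker(), PointSet(obs.points[:4], frame=SENSOR))

    def test_rotation_error_grows_with_noise(self, rig):
        true = pose_at()
        med = {}
        for sigma in (0.2, 1.0):
            errs = []
            for seed in range(150):
                obs = observe_marker(rig, marker(), true, sigma, seed=seed)
                est = estimate_pose(marker(), obs)
                errs.append(rotation_geodesic_deg(est.transform, true))
            med[sigma] = np.median(errs)
        assert med[0.2] < med[1.0]

    def test_translation_estimate_is_unbiased(self, rig):
        # first-order unbiasedness in the tracker's realistic noise regime;
        # at large sigma a second-order depth bias (E[1/disparity] convexity)
        # is expected and not tested here
        true = pose_at()
        errs = np.array(
            [
                estimate_pose(
                    marker(), observe_marker(rig, marker(), true, 0.2, seed=s)
                ).transform.translation
                - true.translation
                for s in range(1000)
            ]
        )
        se = errs.std(axis=0, ddof=1) / np.sqrt(len(errs))
        assert np.all(np.abs(errs.mean(axis=0)) < 3.0 * se + 1e-12)


def five_distinct_templates():
    rng = np.random.default_rng(3)
    db = TemplateDatabase()
    for i in range(5):
        pts = SQUARE5 * (0.8 + 0.15 * i) + rng.uniform(-3, 3, SQUARE5.shape)
        db.add(f"tool{i}", pts)
    return db


class TestIdentifyTemplate:
    def test_self_identification_noise_free(self, rig):
        db = TemplateDatabase([marker("A")])
        obs = observe_marker(rig, db["A"], pose_at(name="A"), 0.0)
        name, pose = identify_template(db, obs)
        assert name == "A"
        assert pose.rms_residual_mm < 1e-8

    def test_distinguishes_by_distance_signature(self, rig):
        db = TemplateDatabase([marker("A"), MarkerTemplate("B", SQUARE5 * 1.3)])
        obs = observe_marker(rig, db["B"], pose_at(name="B"), 0.0)
        assert identify_template(db, obs)[0] == "B"

    def test_scaled_observation_has_no_match(self, rig):
        db = TemplateDatabase([marker("A")])
        obs = observe_marker(rig, db["A"], pose_at(name="A"), 0.0)
        from scopesight.geometry import PointSet

        scaled = PointSet(obs.points * 2.0, frame=SENSOR)
        with pytest.raises(NoMatchError):
            identify_template(db, scaled)

    def test_empty_database(self, rig):
        from scopesight.geometry import PointSet

        with pytest.raises(NoMatchError, match="empty"):
            identify_template(TemplateDatabase(), PointSet(np.zeros((4, 3))))

    def test_many_tools_tracked_simultaneously(self, rig):
        # several distinct tools, all identified per-frame under 0.2 px noise
        db = five_distinct_templates()
        correct = total = 0
        for trial in range(40):
            for i, name in enumerate(db.names()):
                true = RigidTransform(
                    np.eye(3), np.array([60.0 * i - 120.0, 0.0, 600.0]), name, SENSOR
                )
                obs = observe_marker(rig, db[name], true, 0.2, seed=1000 * trial + i)
                # threshold sized for the rig's triangulation noise at this range
                got, _ = identify_template(db, obs, max_residual_mm=2.0)
                correct += got == name
                total += 1
        assert correct / total >= 0.99


class TestTemplateDatabase:
    def test_add_and_size(self):
        db = TemplateDatabase()
        add_template(db, "n", SQUARE5)
        assert len(db) == 1 and "n" in db

    def test_duplicate_name_rejected(self):
        db = TemplateDatabase([marker("n")])
        with pytest.raises(ValueError, match="already registered"):
            db.add("n", SQUARE5)

    def test_degenerate_points_rejected(self):
        db = TemplateDatabase()
        with pytest.raises(ValueError):
            db.add("bad", np.zeros((4, 3)))

    def test_added_template_self_identifies(self, rig):
        db = five_distinct_templates()
        db.add("new", SQUARE5 * 2.0)
        obs = observe_marker(rig, db["new"], pose_at(name="new"), 0.0)
        assert identify_template(db, obs)[0] == "new"

    def test_file_roundtrip(self, tmp_path):
        from scopesight.tracker import load_templates, save_templates

        db = five_distinct_templates()
        path = tmp_path / "templates.json"
        save_templates(db, path)
        back = load_templates(path)
        assert back.names() == db.names()
        for n in db.names():
            np.testing.assert_array_equal(back[n].xpoints, db[n].xpoints)
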