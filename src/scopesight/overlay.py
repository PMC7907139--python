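"""The AR core: per-frame transform chaining, overlay rendering, sessions.

Each video frame, the tracker reports the pose of the base-plate marker
(which defines the model base frame) and of the two scope markers; the lens
cylinder angle is estimated from the head/cylinder marker pair; the chain

    model -> camera  =  camera_from_tip(theta)  o  T_AT  o  invert(T_sA)  o  T_sM

places every organ in the virtual camera sight, whose projection (with the
calibrated lens distortion applied forward, so overlay geometry matches the
distorted endoscopic video) is drawn as a wireframe over the frame. No
hidden-surface removal is performed on purpose: structures behind the joint
capsule are exactly what the surgeon needs superimposed.

A small landmark-based registration refinement stands in for the study's
manual adjustment of the overlay against visible anatomy.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    CAMERA,
    MODEL,
    SCOPE_HEAD,
    SENSOR,
    PointSet,
    RigidTransform,
    absolute_orientation,
    apply,
    compose,
    invert,
    rotation_about_axis,
)
from .endoscope import (
    ArthroscopeGeometry,
    ArthroscopeModel,
    camera_from_tip,
    estimate_cylinder_angle,
    project,
    virtual_camera_pose,
)
from .mesh import OrganModel, TriangleMesh
from .tracker import (
    MarkerTemplate,
    StereoRig,
    TemplateDatabase,
    TrackedPose,
    default_rig,
    estimate_pose,
    observe_marker,
)

__all__ = [
    "Scene",
    "ARFrame",
    "OverlayPrimitive",
    "MissingMarkerError",
    "model_to_camera",
    "render_overlay",
    "refine_registration",
    "SessionConfig",
    "run_session",
    "look_at_camera",
]

log = logging.getLogger(__name__)


class MissingMarkerError(KeyError):
    """A marker required by the scene is absent from the frame's poses."""


def model_to_camera(
    T_sM: RigidTransform,
    T_sA: RigidTransform,
    geom: ArthroscopeGeometry,
    theta_deg: float,
) -> RigidTransform:
    """Transform taking model-base coordinates to camera-sight coordinates.

    ``T_sM`` is the tracked base-plate pose (model base -> sensor), ``T_sA``
    the tracked scope-head pose (head marker -> sensor); frame labels on the
    inputs are normalized to the canonical chain frames, but both must end
    in the sensor frame.
    """
    if T_sM.to_frame != SENSOR or T_sA.to_frame != SENSOR:
        raise ValueError("both tracked poses must map into the sensor frame")
    T_sM = T_sM.with_frames(MODEL, SENSOR)
    T_sA = T_sA.with_frames(SCOPE_HEAD, SENSOR)
    tip_pose = compose(geom.T_AT, invert(T_sA))  # sensor -> tip
    cam_pose = virtual_camera_pose(tip_pose, geom, theta_deg)  # sensor -> camera
    return compose(cam_pose, T_sM)


# -- rendering -------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class OverlayPrimitive:
    """A 2D polyline (here: one clipped edge) tagged with its organ name."""

    organ: str
    points: np.ndarray  # (K,2) px

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if not np.all(np.isfinite(p)):
            raise ValueError("overlay primitive has non-finite coordinates")
        object.__setattr__(self, "points", p)


@dataclasses.dataclass
class ARFrame:
    """One rendered frame: base raster, overlay primitives, composite."""

    index: int
    base: np.ndarray  # (H,W) uint8
    primitives: list[OverlayPrimitive]
    composited: np.ndarray  # (H,W) uint8
    theta_deg: float
    # pre-clip projections of every organ vertex (NaN where behind camera);
    # kept for diagnostics and overlay-accuracy measurement
    vertex_projections: dict[str, np.ndarray]
    # simulator-only ground truth: the commanded model->camera transform
    # (None for frames rendered from real tracked poses)
    camera_from_model_true: "RigidTransform | None" = None


def _clip_segment_to_rect(p0, p1, xmin, xmax, ymin, ymax):
    """Liang-Barsky segment/rect clip; returns (q0, q1) or None if outside."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-d[0], p0[0] - xmin),
        (d[0], xmax - p0[0]),
        (-d[1], p0[1] - ymin),
        (d[1], ymax - p0[1]),
    ):
        if p == 0.0:
            if q < 0.0:
                return None
            continue
        r = q / p
        if p < 0.0:
            if r > t1:
                return None
            t0 = max(t0, r)
        else:
            if r < t0:
                return None
            t1 = min(t1, r)
    lo = np.array([xmin, ymin])
    hi = np.array([xmax, ymax])
    # clamp away float residue so clipped points honour the bounds exactly
    return np.clip(p0 + t0 * d, lo, hi), np.clip(p0 + t1 * d, lo, hi)


def _project_mesh_edges(
    mesh: TriangleMesh,
    T_co: RigidTransform,
    model: ArthroscopeModel,
    organ_name: str,
    near_mm: float = 0.05,
) -> tuple[list[OverlayPrimitive], np.ndarray]:
    """Project a mesh's unique edges; near-plane and image-rect clipped."""
    intr = model.intrinsics
    pc = T_co.transform_points(mesh.vertices)
    z = pc[:, 2]
    visible = z > near_mm
    uv = np.full((pc.shape[0], 2), np.nan)
    if np.any(visible):
        uv[visible] = project(intr, model.distortion, pc[visible])
    prims: list[OverlayPrimitive] = []
    if not np.any(visible):
        return prims, uv
    xmin, xmax = -0.5, intr.width - 0.5
    ymin, ymax = -0.5, intr.height - 0.5
    for a, b in mesh.edges():
        pa, pb = pc[a], pc[b]
        if pa[2] <= near_mm and pb[2] <= near_mm:
            continue
        if pa[2] <= near_mm or pb[2] <= near_mm:
            # clip the edge at the near plane before projecting
            if pa[2] <= near_mm:
                pa, pb = pb, pa
            t = (pa[2] - near_mm) / (pa[2] - pb[2])
            pb = pa + t * (pb - pa)
            qa = project(intr, model.distortion, pa)
            qb = project(intr, model.distortion, pb)
        else:
            qa, qb = uv[a], uv[b]
        seg = _clip_segment_to_rect(
            np.asarray(qa, dtype=float), np.asarray(qb, dtype=float), xmin, xmax, ymin, ymax
        )
        if seg is not None:
            prims.append(OverlayPrimitive(organ_name, np.array(seg)))
    return prims, uv


def _composite(base: np.ndarray, prims: Sequence[OverlayPrimitive]) -> np.ndarray:
    from PIL import Image, ImageDraw

    img = Image.fromarray(base, mode="L")
    draw = ImageDraw.Draw(img)
    for p in prims:
        xy = [tuple(pt) for pt in p.points]
        if len(xy) >= 2:
            draw.line(xy, fill=255, width=1)
    return np.asarray(img)


@dataclasses.dataclass
class Scene:
    """Everything the per-frame overlay computation needs."""

    organs: Sequence[OrganModel]
    database: TemplateDatabase
    base_marker: str
    head_marker: str
    cylinder_marker: str
    scope: ArthroscopeModel
    # reference head/cylinder pose pair captured at theta = 0
    reference: tuple[RigidTransform, RigidTransform] | None = None
    # manual-registration surrogate: correction applied in the model frame
    delta_T: RigidTransform = dataclasses.field(
        default_factory=lambda: RigidTransform.identity(MODEL)
    )

    def __post_init__(self):
        for name in (self.base_marker, self.head_marker, self.cylinder_marker):
            if name not in self.database:
                raise ValueError(f"marker {name!r} not present in the template database")


def render_overlay(
    scene: Scene,
    poses: Mapping[str, TrackedPose],
    frame_index: int = 0,
    base: np.ndarray | None = None,
) -> ARFrame:
    """Render one AR frame from this frame's tracked poses.

    Raises :class:`MissingMarkerError` if a required marker was not tracked
    (callers log and skip the frame). Organs entirely behind the camera
    yield empty primitive lists, not errors.
    """
    for name in (scene.base_marker, scene.head_marker, scene.cylinder_marker):
        if name not in poses:
            raise MissingMarkerError(name)
    T_sM = poses[scene.base_marker].transform
    T_sA = poses[scene.head_marker].transform
    if scene.reference is None:
        raise ValueError("scene has no theta=0 reference pose pair")
    est = estimate_cylinder_angle(
        T_sA, poses[scene.cylinder_marker].transform, scene.reference, scene.scope.geometry
    )
    chain = model_to_camera(T_sM, T_sA, scene.scope.geometry, est.angle_deg)
    intr = scene.scope.intrinsics
    if base is None:
        base = np.full((intr.height, intr.width), 128, dtype=np.uint8)
    prims: list[OverlayPrimitive] = []
    vertex_proj: dict[str, np.ndarray] = {}
    for organ in scene.organs:
        # organ-local -> model (invert T_MO), manual correction, model -> camera
        T_co = compose(chain, compose(scene.delta_T, invert(organ.T_MO)))
        p, uv = _project_mesh_edges(organ.mesh, T_co, scene.scope, organ.name)
        prims.extend(p)
        vertex_proj[organ.name] = uv
    composited = _composite(base, prims)
    return ARFrame(frame_index, base, prims, composited, est.angle_deg, vertex_proj)


def refine_registration(
    scene: Scene,
    landmark_pairs: Sequence[tuple[np.ndarray, np.ndarray]],
) -> tuple[RigidTransform, float]:
    """Landmark-based surrogate for the study's manual overlay adjustment.

    ``landmark_pairs`` are (model-frame point, observed model-frame point)
    3D-3D correspondences, e.g. distinctive anatomy (capitellum, radial
    head) located both in the preoperative model and in the registered
    view. The rigid fit of model landmarks onto observed landmarks becomes
    the scene's correction ``delta_T`` (applied in the model frame, ahead
    of the organ placement); returns (delta_T, rms residual mm).
    """
    src = np.asarray([p[0] for p in landmark_pairs], dtype=float)
    dst = np.asarray([p[1] for p in landmark_pairs], dtype=float)
    t, rms = absolute_orientation(
        PointSet(src, frame=MODEL), PointSet(dst, frame=MODEL)
    )
    scene.delta_T = t
    return t, rms


# -- session orchestration -------------------------------------------------


def look_at_camera(
    center: np.ndarray, target: np.ndarray, roll_deg: float = 0.0
) -> RigidTransform:
    """Sensor->camera transform for a camera at ``center`` looking at ``target``.

    Camera convention +z forward, +x right, +y down; ``roll_deg`` spins the
    image about the optical axis.
    """
    center = np.asarray(center, dtype=float)
    d = np.asarray(target, dtype=float) - center
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e = np.cross(d, helper)
    e /= np.linalg.norm(e)
    x = rotation_about_axis(d, roll_deg).rotation @ e
    y = np.cross(d, x)
    B = np.column_stack([x, y, d])  # camera basis in sensor coordinates
    return RigidTransform(B.T, -B.T @ center, SENSOR, CAMERA)


def ground_truth_marker_poses(
    camera_in_sensor: RigidTransform,
    geom: ArthroscopeGeometry,
    theta_deg: float,
    T_A_cyl0: RigidTransform,
) -> tuple[RigidTransform, RigidTransform]:
    """Head- and cylinder-marker poses consistent with a desired camera pose.

    Works the chain backwards: given the wanted sensor->camera transform
    and the cylinder angle, recover head-marker -> sensor and
    cylinder-marker -> sensor ground truth (the simulator then observes
    those markers with noise).
    """
    T_cs = camera_in_sensor  # sensor -> camera
    T_ct = camera_from_tip(geom, theta_deg)  # tip -> camera
    T_ts = compose(invert(T_ct), T_cs)  # sensor -> tip
    T_as = compose(invert(geom.T_AT), T_ts)  # sensor -> head
    T_sA = invert(T_as)  # head -> sensor
    axis_head = geom.axis_in_head_frame()
    spin = rotation_about_axis(axis_head, theta_deg, SCOPE_HEAD, SCOPE_HEAD)
    T_sCyl = compose(T_sA, compose(spin, T_A_cyl0))
    return T_sA, T_sCyl


@dataclasses.dataclass
class SessionConfig:
    """A simulated examination session.

    The scope is aimed at a fixed target point in the model frame at the
    given working distance while the lens cylinder sweeps through
    ``thetas_deg``; markers are observed through the stereo tracker with
    the configured pixel noise.
    """

    thetas_deg: Sequence[float] = tuple(range(-40, 41, 10))
    noise_sigma_px: float = 0.0
    working_distance_mm: float = 20.0
    target_in_model: tuple[float, float, float] = (20.0, 0.0, 5.0)
    view_direction: tuple[float, float, float] = (0.0, -0.35, -0.94)
    base_pose_translation: tuple[float, float, float] = (0.0, 30.0, 700.0)
    organ_names: Sequence[str] | None = None  # None = all phantom organs

    def validate(self) -> None:
        missing = []
        if not len(tuple(self.thetas_deg)):
            missing.append("thetas_deg")
        if self.noise_sigma_px < 0:
            missing.append("noise_sigma_px (must be >= 0)")
        if self.working_distance_mm <= 0:
            missing.append("working_distance_mm (must be > 0)")
        if missing:
            raise ValueError(f"invalid session config fields: {missing}")


def run_session(
    config: SessionConfig,
    phantom,
    scope: ArthroscopeModel,
    rig: StereoRig | None = None,
    seed: int = 0,
    out_dir=None,
):
    """Run a full simulated session; returns (frames, pose log, skip log).

    Deterministic under a fixed (config, seed) pair. If ``out_dir`` is
    given, writes numbered PGM frames, ``poses.csv`` and ``session.log``.
    """
    config.validate()
    if rig is None:
        rig = default_rig()
    geom = scope.geometry
    db = TemplateDatabase(phantom.templates.values())
    scene = Scene(
        organs=[
            o
            for o in phantom.organs
            if config.organ_names is None or o.name in config.organ_names
        ],
        database=db,
        base_marker="base_plate",
        head_marker="scope_head",
        cylinder_marker="lens_cylinder",
        scope=scope,
    )

    # ground-truth scene placement in the sensor frame
    T_sM = RigidTransform(
        rotation_about_axis((1.0, 0.0, 0.0), 180.0).rotation,
        np.asarray(config.base_pose_translation, dtype=float),
        MODEL,
        SENSOR,
    )
    target_s = T_sM.transform_points(np.asarray(config.target_in_model))
    view_dir = np.asarray(config.view_direction, dtype=float)
    view_dir = T_sM.transform_directions(view_dir)
    view_dir /= np.linalg.norm(view_dir)
    cam_center = target_s - config.working_distance_mm * view_dir

    # theta=0 reference pair, captured noise-free once per session
    cam0 = look_at_camera(cam_center, target_s, roll_deg=0.0)
    ref = ground_truth_marker_poses(cam0, geom, 0.0, phantom.T_A_cyl0)
    scene.reference = ref

    rng = np.random.default_rng(seed)
    frames: list[ARFrame] = []
    pose_rows = []
    skip_log: list[str] = []
    for i, theta in enumerate(config.thetas_deg):
        cam = look_at_camera(cam_center, target_s, roll_deg=theta)
        T_sA_true, T_sCyl_true = ground_truth_marker_poses(
            cam, geom, theta, phantom.T_A_cyl0
        )
        truth = {
            "base_plate": T_sM.with_frames("base_plate", SENSOR),
            "scope_head": T_sA_true.with_frames("scope_head", SENSOR),
            "lens_cylinder": T_sCyl_true.with_frames("lens_cylinder", SENSOR),
        }
        poses: dict[str, TrackedPose] = {}
        for name, true_pose in truth.items():
            obs = observe_marker(
                rig, db[name], true_pose, config.noise_sigma_px, rng=rng
            )
            poses[name] = estimate_pose(db[name], obs, frame_index=i)
        try:
            frame = render_overlay(scene, poses, frame_index=i)
        except MissingMarkerError as exc:
            skip_log.append(f"frame {i}: skipped, missing marker {exc.args[0]!r}")
            continue
        # record ground truth via the commanded camera placement — a path
        # independent of the tracked-pose chain the overlay used
        frame.camera_from_model_true = compose(cam, T_sM)
        frames.append(frame)
        for name, p in poses.items():
            row = {"frame": i, "name": name, "residual_mm": p.rms_residual_mm}
            for j, v in enumerate(p.transform.matrix().ravel()):
                row[f"m{j:02d}"] = v
            pose_rows.append(row)
    pose_log = pd.DataFrame(pose_rows)

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        pose_log.to_csv(
            os.path.join(out_dir, "poses.csv"), index=False, float_format="%.12g"
        )
        for f in frames:
            _write_pgm(os.path.join(out_dir, f"frame_{f.index:04d}.pgm"), f.composited)
        with open(os.path.join(out_dir, "session.log"), "w") as fh:
            fh.write(f"frames rendered: {len(frames)}\n")
            for line in skip_log:
                fh.write(line + "\n")
    return frames, pose_log, skip_log


def _write_pgm(path, image: np.ndarray) -> None:
    """Binary PGM (P5): trivially byte-deterministic raster output."""
    h, w = image.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n255\n".encode("ascii"))
        fh.write(np.ascontiguousarray(image, dtype=np.uint8).tobytes())
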