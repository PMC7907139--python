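"""Simulated stereo optical pose tracker.

Stands in for the hardware tracking head: each tool carries a rigid
constellation of high-contrast "Xpoint" targets; the tracker stereo-
triangulates every Xpoint into its sensor frame, fits a rigid transform to
the named template, and reports the tool pose with its RMS fit residual.
Templates live in a run-time database that tools can be added to by name,
and any number of tools can be tracked simultaneously.

Image-level Xpoint detection is firmware in the real device and is not
simulated; observed Xpoints enter as ideal projections perturbed by i.i.d.
Gaussian pixel noise of configurable sigma.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np

from .geometry import (
    SENSOR,
    DegenerateGeometryError,
    PointSet,
    RigidTransform,
    absolute_orientation,
    apply,
    invert,
)
from .endoscope import CameraIntrinsics, DistortionModel, project

__all__ = [
    "MarkerTemplate",
    "StereoRig",
    "TrackedPose",
    "TemplateDatabase",
    "NoMatchError",
    "VisibilityError",
    "DegenerateTriangulationError",
    "default_rig",
    "triangulate",
    "observe_marker",
    "estimate_pose",
    "identify_template",
]

_NO_DISTORTION = DistortionModel()


class NoMatchError(LookupError):
    """No template in the database fits the observation within tolerance."""


class VisibilityError(ValueError):
    """One or more Xpoints are not visible to both rig cameras."""


class DegenerateTriangulationError(ValueError):
    """Back-projected rays are too close to parallel to intersect stably."""


@dataclasses.dataclass(frozen=True)
class MarkerTemplate:
    """Named rigid Xpoint constellation in the marker-local frame (mm).

    At least four points, non-collinear, pairwise separated by >= 1 mm
    (the physical targets cannot overlap).
    """

    name: str
    xpoints: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.xpoints, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("xpoints must be (N,3)")
        if pts.shape[0] < 4:
            raise ValueError(f"template {self.name!r} needs >= 4 xpoints")
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1.0:
            raise ValueError(
                f"template {self.name!r}: xpoints closer than 1 mm "
                f"(min distance {d.min():.3f} mm)"
            )
        c = pts - pts.mean(axis=0)
        sing = np.linalg.svd(c, compute_uv=False)
        if sing[1] <= 1e-9 * max(sing[0], 1.0):
            raise ValueError(f"template {self.name!r}: xpoints are collinear")
        pts.setflags(write=False)
        object.__setattr__(self, "xpoints", pts)

    def __len__(self) -> int:
        return self.xpoints.shape[0]

    def as_pointset(self) -> PointSet:
        return PointSet(self.xpoints, frame=self.name)


@dataclasses.dataclass(frozen=True)
class StereoRig:
    """Two pinhole cameras rigidly mounted in the tracker sensor frame.

    ``left_pose``/``right_pose`` map each camera frame to the sensor frame
    (camera convention: +z forward, +x right, +y down).
    """

    left: CameraIntrinsics
    right: CameraIntrinsics
    left_pose: RigidTransform
    right_pose: RigidTransform

    def __post_init__(self):
        if np.allclose(self.left_pose.translation, self.right_pose.translation):
            raise ValueError("camera centres coincide; rig has no baseline")

    @property
    def baseline_mm(self) -> float:
        return float(
            np.linalg.norm(self.left_pose.translation - self.right_pose.translation)
        )


def default_rig(
    baseline_mm: float = 120.0,
    convergence_deg: float = 10.0,
    f_px: float = 1000.0,
    width: int = 1280,
    height: int = 960,
) -> StereoRig:
    """Plausible desk-scale tracker head: two identical converged cameras.

    Cameras sit at x = -/+ baseline/2 in the sensor frame, each toed in by
    half the convergence angle so their axes cross in front of the rig.
    """
    intr = CameraIntrinsics(f_px, f_px, (width - 1) / 2.0, (height - 1) / 2.0, width, height)
    half = np.deg2rad(convergence_deg / 2.0)

    def cam_pose(x_off: float, yaw: float) -> RigidTransform:
        cy, sy = np.cos(yaw), np.sin(yaw)
        R = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
        return RigidTransform(R, np.array([x_off, 0.0, 0.0]), "camera", SENSOR)

    return StereoRig(
        left=intr,
        right=intr,
        left_pose=cam_pose(-baseline_mm / 2.0, +half),
        right_pose=cam_pose(+baseline_mm / 2.0, -half),
    )


def _project_to_camera(
    rig_cam: CameraIntrinsics, cam_pose: RigidTransform, p_sensor: np.ndarray
) -> np.ndarray:
    p_cam = invert(cam_pose).transform_points(p_sensor)
    return project(rig_cam, _NO_DISTORTION, p_cam)


def triangulate(
    rig: StereoRig, left_px: np.ndarray, right_px: np.ndarray
) -> np.ndarray:
    """3D point (mm, sensor frame) from one pixel pair.

    Back-projects one ray per camera and returns the midpoint of the
    shortest segment between them; rays within 0.1 degree of parallel raise
    :class:`DegenerateTriangulationError`.
    """
    left_px = np.asarray(left_px, dtype=float).reshape(2)
    right_px = np.asarray(right_px, dtype=float).reshape(2)
    for intr, px, side in ((rig.left, left_px, "left"), (rig.right, right_px, "right")):
        if not bool(intr.pixel_in_bounds(px)[0]):
            raise ValueError(f"{side} pixel {px.tolist()} outside image bounds")

    def ray(intr: CameraIntrinsics, pose: RigidTransform, px):
        d_cam = np.array([(px[0] - intr.cx) / intr.fx, (px[1] - intr.cy) / intr.fy, 1.0])
        d = pose.transform_directions(d_cam)
        return pose.translation, d / np.linalg.norm(d)

    o1, d1 = ray(rig.left, rig.left_pose, left_px)
    o2, d2 = ray(rig.right, rig.right_pose, right_px)
    cosang = np.clip(abs(np.dot(d1, d2)), 0.0, 1.0)
    if np.degrees(np.arccos(cosang)) < 0.1:
        raise DegenerateTriangulationError(
            "rays are near-parallel (< 0.1 deg); cannot triangulate"
        )
    # closest points: solve [d1.d1  -d1.d2; d1.d2  -d2.d2] [s;t] = [(o2-o1).d1; (o2-o1).d2]
    w = o2 - o1
    a = np.dot(d1, d1)
    b = np.dot(d1, d2)
    c = np.dot(d2, d2)
    s = (np.dot(w, d1) * c - np.dot(w, d2) * b) / (a * c - b * b)
    t = (np.dot(w, d1) * b - np.dot(w, d2) * a) / (a * c - b * b)
    return 0.5 * ((o1 + s * d1) + (o2 + t * d2))


def observe_marker(
    rig: StereoRig,
    template: MarkerTemplate,
    true_pose: RigidTransform,
    noise_sigma_px: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PointSet:
    """Simulate one tracker observation of a marker.

    The template's Xpoints are placed by ``true_pose`` (marker-local ->
    sensor), projected into both cameras, perturbed by i.i.d. Gaussian
    pixel noise, and triangulated back into the sensor frame. Deterministic
    for a fixed seed (or caller-supplied generator). Xpoints behind either
    camera raise :class:`VisibilityError` naming the offending indices.
    """
    if noise_sigma_px < 0:
        raise ValueError("noise_sigma_px must be >= 0")
    if noise_sigma_px > 0 and seed is None and rng is None:
        raise ValueError("noisy observation requires a seed or rng")
    if rng is None:
        rng = np.random.default_rng(seed)
    p_sensor = true_pose.transform_points(template.xpoints)
    for pose, side in ((rig.left_pose, "left"), (rig.right_pose, "right")):
        z = invert(pose).transform_points(p_sensor)[:, 2]
        behind = np.nonzero(z <= 0)[0]
        if behind.size:
            raise VisibilityError(
                f"xpoints {behind.tolist()} of {template.name!r} are behind "
                f"the {side} camera"
            )
    lp = _project_to_camera(rig.left, rig.left_pose, p_sensor)
    rp = _project_to_camera(rig.right, rig.right_pose, p_sensor)
    if noise_sigma_px > 0:
        lp = lp + rng.normal(0.0, noise_sigma_px, size=lp.shape)
        rp = rp + rng.normal(0.0, noise_sigma_px, size=rp.shape)
    pts = np.array([triangulate(rig, lp[i], rp[i]) for i in range(len(template))])
    return PointSet(pts, frame=SENSOR)


@dataclasses.dataclass(frozen=True)
class TrackedPose:
    """Estimated pose of a named marker: marker-local -> sensor frame."""

    template_name: str
    transform: RigidTransform
    rms_residual_mm: float
    frame_index: int = 0

    def __post_init__(self):
        if self.rms_residual_mm < 0:
            raise ValueError("residual must be >= 0")


def estimate_pose(
    template: MarkerTemplate, observed: PointSet, frame_index: int = 0
) -> TrackedPose:
    """Rigid fit of the template onto triangulated Xpoints (index-matched)."""
    if len(observed) != len(template):
        raise ValueError(
            f"observation has {len(observed)} points, template "
            f"{template.name!r} has {len(template)}"
        )
    transform, rms = absolute_orientation(
        PointSet(template.xpoints, frame=template.name), observed
    )
    return TrackedPose(template.name, transform, rms, frame_index)


class TemplateDatabase:
    """Run-time marker-template registry (unique names; updatable live)."""

    def __init__(self, templates: Iterable[MarkerTemplate] = ()):
        self._templates: dict[str, MarkerTemplate] = {}
        for t in templates:
            self.add(t.name, t.xpoints)

    def add(self, name: str, xpoints: np.ndarray) -> MarkerTemplate:
        """Register a new named template; duplicate names are rejected."""
        if name in self._templates:
            raise ValueError(f"template name {name!r} already registered")
        t = MarkerTemplate(name, np.asarray(xpoints, dtype=float))
        self._templates[name] = t
        return t

    def __getitem__(self, name: str) -> MarkerTemplate:
        return self._templates[name]

    def __contains__(self, name: str) -> bool:
        return name in self._templates

    def __len__(self) -> int:
        return len(self._templates)

    def names(self) -> list[str]:
        return sorted(self._templates)

    def templates(self) -> list[MarkerTemplate]:
        return [self._templates[n] for n in self.names()]


def add_template(db: TemplateDatabase, name: str, xpoints: np.ndarray) -> TemplateDatabase:
    """Functional wrapper over :meth:`TemplateDatabase.add` (mutates and returns db)."""
    db.add(name, xpoints)
    return db


def identify_template(
    db: TemplateDatabase,
    observed: PointSet,
    max_residual_mm: float = 1.0,
    frame_index: int = 0,
) -> tuple[str, TrackedPose]:
    """Identify which registered marker produced an observation.

    Fits every template with a matching point count and returns the one
    with the smallest RMS residual (ties broken by name order). If the best
    residual exceeds ``max_residual_mm`` — e.g. the observation is a scaled
    or distorted constellation no rigid fit can absorb — raises
    :class:`NoMatchError`.
    """
    if len(db) == 0:
        raise NoMatchError("template database is empty")
    best: TrackedPose | None = None
    for t in db.templates():  # name-sorted: lexicographic tie-break for free
        if len(t) != len(observed):
            continue
        try:
            pose = estimate_pose(t, observed, frame_index)
        except DegenerateGeometryError:
            continue
        if best is None or pose.rms_residual_mm < best.rms_residual_mm:
            best = pose
    if best is None or best.rms_residual_mm > max_residual_mm:
        res = "none fit" if best is None else f"best residual {best.rms_residual_mm:.3f} mm"
        raise NoMatchError(
            f"no template matches the observation ({res}, "
            f"threshold {max_residual_mm} mm)"
        )
    return best.template_name, best


# -- marker-template file I/O ---------------------------------------------


def save_templates(db: TemplateDatabase, path) -> None:
    """JSON file: list of {name, xpoints: Nx3 mm}."""
    import json

    payload = [
        {"name": t.name, "xpoints": t.xpoints.tolist()} for t in db.templates()
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_templates(path) -> TemplateDatabase:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    db = TemplateDatabase()
    for entry in payload:
        db.add(entry["name"], np.asarray(entry["xpoints"], dtype=float))
    return db
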