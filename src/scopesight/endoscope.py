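"""Oblique-viewing arthroscope camera model.

An angled arthroscope views along an optical axis tilted from the mechanical
shaft by the lens-offset angle (30 degrees for the scopes modelled here).
Rotating the lens cylinder by an azimuth theta sweeps the viewing direction
around a cone of that half-angle; the image rotates with the cylinder. This
module provides:

* pinhole intrinsics and the Brown-Conrady radial-tangential distortion
  model, with forward distortion and iterative reverse correction (the
  "reverse distortion" step that makes overlay geometry match the distorted
  endoscopic video);
* projection of camera-frame 3D points to pixels;
* the virtual-camera pose as a function of cylinder angle theta;
* estimation of theta from the relative pose between a marker on the camera
  head and a marker on the lens cylinder.

Planar-target calibration that estimates intrinsics and distortion lives in
:mod:`scopesight.calibration`.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from .geometry import (
    CAMERA,
    SCOPE_HEAD,
    TIP,
    RigidTransform,
    compose,
    invert,
    rotation_about_axis,
)

__all__ = [
    "CameraIntrinsics",
    "DistortionModel",
    "ArthroscopeGeometry",
    "ArthroscopeModel",
    "CylinderAngleEstimate",
    "NonConvergenceError",
    "distort",
    "undistort",
    "project",
    "camera_from_tip",
    "virtual_camera_pose",
    "estimate_cylinder_angle",
    "save_arthroscope_model",
    "load_arthroscope_model",
]


class NonConvergenceError(RuntimeError):
    """Reverse distortion failed to converge; carries the final residual."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"undistortion did not converge below tolerance after "
            f"{max_iter} iterations (residual {residual:.3e})"
        )
        self.residual = residual


@dataclasses.dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics in pixels; principal point must lie inside the image."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def pixel_in_bounds(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(uv)
        return (
            (uv[:, 0] >= -0.5)
            & (uv[:, 0] <= self.width - 0.5)
            & (uv[:, 1] >= -0.5)
            & (uv[:, 1] <= self.height - 0.5)
        )


@dataclasses.dataclass(frozen=True)
class DistortionModel:
    """Brown-Conrady distortion: radial k1, k2, k3 and tangential p1, p2.

    Operates on normalized image coordinates (x/z, y/z). Negative k1 gives
    barrel distortion, the typical case for wide-angle arthroscope optics.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    @property
    def is_zero(self) -> bool:
        return self.k1 == self.k2 == self.k3 == self.p1 == self.p2 == 0.0

    def coeffs(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.p1, self.p2])

    def check_injective(self, r_max: float = 1.0, n: int = 400) -> bool:
        """Numerically check the distorted radius is increasing on [0, r_max].

        A monotone radial profile (plus small tangential terms) makes the
        mapping invertible over the calibrated field of view.
        """
        r = np.linspace(0.0, r_max, n)
        rd = r * (1.0 + self.k1 * r**2 + self.k2 * r**4 + self.k3 * r**6)
        return bool(np.all(np.diff(rd) > 0.0))


def distort(d: DistortionModel, xn: np.ndarray) -> np.ndarray:
    """Forward Brown-Conrady model on normalized points (shape (...,2))."""
    xn = np.asarray(xn, dtype=float)
    x = xn[..., 0]
    y = xn[..., 1]
    r2 = x * x + y * y
    radial = 1.0 + d.k1 * r2 + d.k2 * r2**2 + d.k3 * r2**3
    xd = x * radial + 2.0 * d.p1 * x * y + d.p2 * (r2 + 2.0 * x * x)
    yd = y * radial + d.p1 * (r2 + 2.0 * y * y) + 2.0 * d.p2 * x * y
    return np.stack([xd, yd], axis=-1)


def undistort(
    d: DistortionModel,
    xd: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> np.ndarray:
    """Reverse distortion by fixed-point iteration.

    Iterates ``x <- (xd - tangential(x)) / radial(x)`` from ``x0 = xd``;
    stops when ``max ||distort(x) - xd|| < tol``. Raises
    :class:`NonConvergenceError` if the tolerance is not reached.
    """
    xd = np.asarray(xd, dtype=float)
    x = xd.copy()
    residual = np.inf
    for _ in range(max_iter):
        xc = x[..., 0]
        yc = x[..., 1]
        r2 = xc * xc + yc * yc
        radial = 1.0 + d.k1 * r2 + d.k2 * r2**2 + d.k3 * r2**3
        tx = 2.0 * d.p1 * xc * yc + d.p2 * (r2 + 2.0 * xc * xc)
        ty = d.p1 * (r2 + 2.0 * yc * yc) + 2.0 * d.p2 * xc * yc
        x = np.stack([(xd[..., 0] - tx) / radial, (xd[..., 1] - ty) / radial], axis=-1)
        err = distort(d, x) - xd
        residual = float(np.max(np.sqrt(np.sum(err**2, axis=-1)))) if err.size else 0.0
        if residual < tol:
            return x
    raise NonConvergenceError(residual, max_iter)


def project(
    intr: CameraIntrinsics,
    d: DistortionModel,
    p_cam: np.ndarray,
    min_depth: float = 1e-9,
) -> np.ndarray:
    """Project camera-frame points (mm) to pixels: divide, distort, intrinsics.

    Camera convention: +z forward (optical axis), +x right, +y down.
    Points must have positive depth; pixels may fall outside the image
    (use :meth:`CameraIntrinsics.pixel_in_bounds` to flag them).
    """
    p = np.asarray(p_cam, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    z = p[:, 2]
    if np.any(z <= min_depth):
        bad = np.nonzero(z <= min_depth)[0]
        raise ValueError(f"non-positive depth for point indices {bad.tolist()}")
    xn = p[:, :2] / z[:, None]
    xd = distort(d, xn)
    uv = np.stack(
        [intr.fx * xd[:, 0] + intr.cx, intr.fy * xd[:, 1] + intr.cy], axis=-1
    )
    return uv[0] if single else uv


def backproject_ray(
    intr: CameraIntrinsics, d: DistortionModel, uv: np.ndarray
) -> np.ndarray:
    """Unit ray direction in the camera frame through a (distorted-image) pixel."""
    uv = np.asarray(uv, dtype=float)
    xd = np.stack(
        [(uv[..., 0] - intr.cx) / intr.fx, (uv[..., 1] - intr.cy) / intr.fy], axis=-1
    )
    xn = undistort(d, xd, tol=1e-12)
    ray = np.concatenate([xn, np.ones(xn.shape[:-1] + (1,))], axis=-1)
    return ray / np.linalg.norm(ray, axis=-1, keepdims=True)


def _perpendicular_unit(axis: np.ndarray) -> np.ndarray:
    """Deterministic unit vector perpendicular to ``axis``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e = np.cross(axis, helper)
    return e / np.linalg.norm(e)


@dataclasses.dataclass(frozen=True)
class ArthroscopeGeometry:
    """Mechanical geometry of the angled scope.

    ``T_AT`` maps scope-head-marker coordinates to scope-tip coordinates
    (the rigid mount, measured once per session); ``scope_axis`` is the
    shaft direction in the tip frame; ``lens_offset_deg`` is the fixed tilt
    of the optical axis off the shaft (30 degrees for the standard angled
    arthroscope); ``cylinder_angle_deg`` is the nominal cylinder azimuth the
    geometry was configured at (the live angle is estimated per frame).
    """

    lens_offset_deg: float = 30.0
    T_AT: RigidTransform = dataclasses.field(
        default_factory=lambda: RigidTransform.identity(TIP).with_frames(SCOPE_HEAD, TIP)
    )
    scope_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    cylinder_angle_deg: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.lens_offset_deg < 90.0):
            raise ValueError("lens_offset_deg must be in (0, 90)")
        ax = np.asarray(self.scope_axis, dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
            raise ValueError("scope_axis must be a unit vector")
        if self.T_AT.from_frame != SCOPE_HEAD or self.T_AT.to_frame != TIP:
            raise ValueError("T_AT must map scope_head -> tip")

    @property
    def axis(self) -> np.ndarray:
        return np.asarray(self.scope_axis, dtype=float)

    def axis_in_head_frame(self) -> np.ndarray:
        """Shaft direction expressed in the scope-head-marker frame."""
        return self.T_AT.rotation.T @ self.axis


@dataclasses.dataclass(frozen=True)
class ArthroscopeModel:
    """Complete camera model: intrinsics + distortion + scope geometry."""

    intrinsics: CameraIntrinsics
    distortion: DistortionModel
    geometry: ArthroscopeGeometry


def camera_from_tip(geom: ArthroscopeGeometry, theta_deg: float) -> RigidTransform:
    """Transform tip -> camera-sight for cylinder angle ``theta_deg``.

    The camera centre sits at the tip origin. At theta = 0 the optical axis
    is the shaft axis tilted by the lens-offset angle about a fixed
    perpendicular; increasing theta rotates the whole camera (axis and
    up-vector together) about the shaft, so the optical axis sweeps a cone
    of half-angle ``lens_offset_deg`` and the image rotates with the
    cylinder.
    """
    axis = geom.axis
    e = _perpendicular_unit(axis)
    # camera axes in tip frame at theta=0, before tilt: x->e, y->axis x e, z->axis
    B = np.column_stack([e, np.cross(axis, e), axis])
    tilt = rotation_about_axis(e, geom.lens_offset_deg).rotation
    spin = rotation_about_axis(axis, theta_deg).rotation
    R_tc = spin @ tilt @ B  # camera basis expressed in tip coordinates
    return RigidTransform(R_tc.T, np.zeros(3), TIP, CAMERA)


def virtual_camera_pose(
    tip_pose: RigidTransform, geom: ArthroscopeGeometry, theta_deg: float
) -> RigidTransform:
    """Pose of the virtual camera sight: maps ``tip_pose.from_frame`` -> camera.

    ``tip_pose`` maps some frame (typically the tracker sensor) to the tip;
    the result prepends the tip->camera transform for cylinder angle theta.
    """
    if tip_pose.to_frame != TIP:
        raise ValueError(f"tip_pose must end in frame {TIP!r}, got {tip_pose.to_frame!r}")
    return compose(camera_from_tip(geom, theta_deg), tip_pose)


def optical_axis_in_tip_frame(geom: ArthroscopeGeometry, theta_deg: float) -> np.ndarray:
    """Viewing direction (unit, tip frame) at cylinder angle theta."""
    R_ct = camera_from_tip(geom, theta_deg).rotation.T  # camera -> tip
    return R_ct @ np.array([0.0, 0.0, 1.0])


@dataclasses.dataclass(frozen=True)
class CylinderAngleEstimate:
    """Estimated cylinder rotation angle, with an axis-consistency flag.

    ``misaligned`` is set when the relative head->cylinder rotation axis
    deviates from the shaft axis by more than the tolerance, which signals
    a bent mount or a badly tracked marker rather than a pure cylinder spin.
    """

    angle_deg: float
    misaligned: bool
    axis_deviation_deg: float


def _as_transform(pose) -> RigidTransform:
    if isinstance(pose, RigidTransform):
        return pose
    t = getattr(pose, "transform", None)
    if isinstance(t, RigidTransform):
        return t
    raise TypeError(f"expected RigidTransform or TrackedPose, got {type(pose)!r}")


def estimate_cylinder_angle(
    head_pose,
    cyl_pose,
    reference: tuple,
    geom: ArthroscopeGeometry,
    axis_tol_deg: float = 5.0,
) -> CylinderAngleEstimate:
    """Cylinder rotation angle from the head-marker / cylinder-marker pair.

    The relative transform head->cylinder is compared against a reference
    pair captured once at theta = 0; the incremental rotation is decomposed
    into an angle about the shaft axis (expressed in the head-marker frame).
    Returns the signed angle in (-180, 180] plus a misalignment flag when
    the incremental rotation axis deviates from the shaft axis by more than
    ``axis_tol_deg``.
    """
    T_sA = _as_transform(head_pose)
    T_sC = _as_transform(cyl_pose)
    T_sA0 = _as_transform(reference[0])
    T_sC0 = _as_transform(reference[1])
    rel = compose(invert(T_sA), T_sC.with_frames(T_sC.from_frame, T_sA.to_frame))
    rel0 = compose(invert(T_sA0), T_sC0.with_frames(T_sC0.from_frame, T_sA0.to_frame))
    delta = compose(rel, invert(rel0).with_frames(rel.to_frame, rel0.from_frame))

    from scipy.spatial.transform import Rotation as _Rot

    rotvec = _Rot.from_matrix(delta.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    axis_head = geom.axis_in_head_frame()
    if angle < 1e-12:
        return CylinderAngleEstimate(0.0, False, 0.0)
    axis = rotvec / angle
    cosd = float(np.clip(abs(np.dot(axis, axis_head)), -1.0, 1.0))
    deviation = float(np.degrees(np.arccos(cosd)))
    signed = float(np.degrees(angle)) * float(np.sign(np.dot(axis, axis_head)))
    if signed <= -180.0:
        signed += 360.0
    return CylinderAngleEstimate(signed, deviation > axis_tol_deg, deviation)


# -- serialization ---------------------------------------------------------


def save_arthroscope_model(model: ArthroscopeModel, path) -> None:
    """Write the calibration file: intrinsics, distortion, offset angle, T_AT."""
    intr, d, g = model.intrinsics, model.distortion, model.geometry
    payload = {
        "fx": intr.fx,
        "fy": intr.fy,
        "cx": intr.cx,
        "cy": intr.cy,
        "width": intr.width,
        "height": intr.height,
        "k1": d.k1,
        "k2": d.k2,
        "k3": d.k3,
        "p1": d.p1,
        "p2": d.p2,
        "lens_offset_deg": g.lens_offset_deg,
        "scope_axis": list(g.axis),
        "T_AT": [float(x) for x in g.T_AT.matrix().ravel()],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_arthroscope_model(path) -> ArthroscopeModel:
    with open(path) as fh:
        d = json.load(fh)
    intr = CameraIntrinsics(d["fx"], d["fy"], d["cx"], d["cy"], d["width"], d["height"])
    dist = DistortionModel(d["k1"], d["k2"], d["k3"], d["p1"], d["p2"])
    T_AT = RigidTransform.from_matrix(
        np.asarray(d["T_AT"], dtype=float).reshape(4, 4), SCOPE_HEAD, TIP
    )
    geom = ArthroscopeGeometry(
        lens_offset_deg=d["lens_offset_deg"],
        T_AT=T_AT,
        scope_axis=tuple(d.get("scope_axis", (0.0, 0.0, 1.0))),
    )
    return ArthroscopeModel(intr, dist, geom)
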