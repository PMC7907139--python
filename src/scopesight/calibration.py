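"""Planar-target camera calibration for the arthroscope.

Estimates pinhole intrinsics and Brown-Conrady distortion from several views
of a planar checkerboard, the standard calibration-pattern workflow:

1. a homography is fitted per view (normalized DLT);
2. intrinsics are initialized in closed form from the homography
   constraints on the image of the absolute conic;
3. per-view poses follow from each homography and the intrinsics;
4. everything (intrinsics, distortion, poses) is refined jointly by
   trust-region nonlinear least squares on the reprojection residuals.

Views are correspondence sets of (planar 3D corner, observed pixel); corner
detection from images is out of scope — the synthetic view generator at the
bottom renders correspondences from a known camera, which makes the whole
estimator testable against ground truth.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import CAMERA, WORLD, RigidTransform
from .endoscope import CameraIntrinsics, DistortionModel, distort, project

__all__ = [
    "CalibrationView",
    "CalibrationResult",
    "CalibrationError",
    "calibrate",
    "checkerboard_corners",
    "synthetic_checkerboard_views",
]


class CalibrationError(ValueError):
    """Insufficient or degenerate calibration input."""


@dataclasses.dataclass(frozen=True)
class CalibrationView:
    """One view: planar corners (mm, board frame, Z=0) and observed pixels."""

    object_points: np.ndarray  # (N,3), Z == 0
    image_points: np.ndarray  # (N,2) px

    def __post_init__(self):
        op = np.asarray(self.object_points, dtype=float)
        ip = np.asarray(self.image_points, dtype=float)
        if op.ndim != 2 or op.shape[1] != 3:
            raise ValueError("object_points must be (N,3)")
        if ip.shape != (op.shape[0], 2):
            raise ValueError("image_points must be (N,2) matching object_points")
        if not np.allclose(op[:, 2], 0.0, atol=1e-12):
            raise ValueError("calibration target must be planar with Z=0")
        object.__setattr__(self, "object_points", op)
        object.__setattr__(self, "image_points", ip)


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    intrinsics: CameraIntrinsics
    distortion: DistortionModel
    poses: tuple[RigidTransform, ...]  # board frame -> camera, per view
    rms_px: float
    n_iterations: int


def _homography(obj_xy: np.ndarray, img: np.ndarray) -> np.ndarray:
    """Normalized DLT homography mapping board (X,Y) to pixels."""

    def normalizer(p):
        c = p.mean(axis=0)
        s = np.sqrt(2.0) / max(np.mean(np.linalg.norm(p - c, axis=1)), 1e-12)
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
        return T

    To = normalizer(obj_xy)
    Ti = normalizer(img)
    n = obj_xy.shape[0]
    oh = np.column_stack([obj_xy, np.ones(n)]) @ To.T
    ih = np.column_stack([img, np.ones(n)]) @ Ti.T
    A = np.zeros((2 * n, 9))
    A[0::2, 0:3] = oh
    A[0::2, 6:9] = -ih[:, [0]] * oh
    A[1::2, 3:6] = oh
    A[1::2, 6:9] = -ih[:, [1]] * oh
    _, _, Vt = np.linalg.svd(A)
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Ti) @ H @ To
    return H / H[2, 2]


def _vij(H: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array(
        [
            H[0, i] * H[0, j],
            H[0, i] * H[1, j] + H[1, i] * H[0, j],
            H[1, i] * H[1, j],
            H[2, i] * H[0, j] + H[0, i] * H[2, j],
            H[2, i] * H[1, j] + H[1, i] * H[2, j],
            H[2, i] * H[2, j],
        ]
    )


def _intrinsics_from_homographies(Hs: Sequence[np.ndarray]) -> np.ndarray:
    """Closed-form K (fx, fy, cx, cy; skew discarded) from >= 3 homographies."""
    V = []
    for H in Hs:
        V.append(_vij(H, 0, 1))
        V.append(_vij(H, 0, 0) - _vij(H, 1, 1))
    V = np.asarray(V)
    _, _, Vt = np.linalg.svd(V)
    B11, B12, B22, B13, B23, B33 = Vt[-1]
    denom = B11 * B22 - B12**2
    if abs(denom) < 1e-20 or abs(B11) < 1e-20:
        raise CalibrationError("degenerate view configuration (conic is singular)")
    v0 = (B12 * B13 - B11 * B23) / denom
    lam = B33 - (B13**2 + v0 * (B12 * B13 - B11 * B23)) / B11
    if lam / B11 <= 0 or lam * B11 / denom <= 0:
        raise CalibrationError("degenerate view configuration (negative focal^2)")
    fx = float(np.sqrt(lam / B11))
    fy = float(np.sqrt(lam * B11 / denom))
    gamma = -B12 * fx**2 * fy / lam
    u0 = float(gamma * v0 / fy - B13 * fx**2 / lam)
    return np.array([fx, fy, u0, float(v0)])


def _pose_from_homography(K: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    r1 = lam * Kinv @ h1
    r2 = lam * Kinv @ h2
    t = lam * Kinv @ h3
    if t[2] < 0:  # board must be in front of the camera
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    Q = np.column_stack([r1, r2, r3])
    U, _, Vt = np.linalg.svd(Q)
    R = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
    return R, t


def calibrate(
    views: Sequence[CalibrationView],
    image_size: tuple[int, int],
    min_corners: int = 20,
    max_nfev: int = 200,
    xtol: float = 1e-12,
) -> CalibrationResult:
    """Estimate intrinsics, distortion and per-view poses from planar views.

    Requires >= 3 views of >= ``min_corners`` corners each in non-degenerate
    orientations. Returns the refined parameters and the RMS reprojection
    error in pixels.
    """
    if len(views) < 3:
        raise CalibrationError(f"need >= 3 views, got {len(views)}")
    for i, v in enumerate(views):
        if v.object_points.shape[0] < min_corners:
            raise CalibrationError(
                f"view {i} has {v.object_points.shape[0]} corners, "
                f"need >= {min_corners}"
            )

    Hs = [_homography(v.object_points[:, :2], v.image_points) for v in views]
    fx, fy, cx, cy = _intrinsics_from_homographies(Hs)
    K = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1.0]])
    pose_params = []
    for H in Hs:
        R, t = _pose_from_homography(K, H)
        pose_params.append(np.concatenate([Rotation.from_matrix(R).as_rotvec(), t]))

    width, height = image_size
    x0 = np.concatenate([[fx, fy, cx, cy, 0, 0, 0, 0, 0], *pose_params])
    n_views = len(views)

    def residuals(x):
        fx_, fy_, cx_, cy_ = x[:4]
        k1, k2, k3, p1, p2 = x[4:9]
        out = []
        for i, v in enumerate(views):
            rv = x[9 + 6 * i : 12 + 6 * i]
            tv = x[12 + 6 * i : 15 + 6 * i]
            R = Rotation.from_rotvec(rv).as_matrix()
            pc = v.object_points @ R.T + tv
            xn = pc[:, :2] / pc[:, 2:3]
            xd = distort(DistortionModel(k1, k2, k3, p1, p2), xn)
            u = fx_ * xd[:, 0] + cx_
            vpx = fy_ * xd[:, 1] + cy_
            out.append(u - v.image_points[:, 0])
            out.append(vpx - v.image_points[:, 1])
        return np.concatenate(out)

    sol = least_squares(
        residuals, x0, method="trf", xtol=xtol, ftol=xtol, gtol=xtol, max_nfev=max_nfev
    )
    x = sol.x
    intr = CameraIntrinsics(x[0], x[1], x[2], x[3], width, height)
    dist = DistortionModel(*x[4:9])
    poses = []
    for i in range(n_views):
        R = Rotation.from_rotvec(x[9 + 6 * i : 12 + 6 * i]).as_matrix()
        poses.append(
            RigidTransform(R, x[12 + 6 * i : 15 + 6 * i], from_frame="board", to_frame=CAMERA)
        )
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return CalibrationResult(intr, dist, tuple(poses), rms, int(sol.nfev))


# -- synthetic fixtures ----------------------------------------------------


def checkerboard_corners(nx: int = 8, ny: int = 6, square_mm: float = 2.0) -> np.ndarray:
    """Inner-corner grid of an nx-by-ny checkerboard, Z=0, board frame (mm)."""
    xs, ys = np.meshgrid(np.arange(nx) * square_mm, np.arange(ny) * square_mm)
    return np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])


def synthetic_checkerboard_views(
    intr: CameraIntrinsics,
    dist: DistortionModel,
    n_views: int = 10,
    nx: int = 8,
    ny: int = 6,
    square_mm: float = 4.0,
    distance_mm: float = 30.0,
    noise_sigma_px: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[CalibrationView], list[RigidTransform]]:
    """Render correspondence sets for a known camera.

    Boards are placed in front of the camera at ``distance_mm`` with varied
    tilts (up to ~35 degrees about in-plane axes) and rolls, mimicking a
    hand-held calibration sweep; optional i.i.d. Gaussian pixel noise.
    Returns the views plus the ground-truth board->camera poses.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    corners = checkerboard_corners(nx, ny, square_mm)
    centre = corners.mean(axis=0)
    views, poses = [], []
    for i in range(n_views):
        # deterministic tilt schedule + random jitter: guarantees that views
        # are not all fronto-parallel (which would be degenerate for Zhang)
        tilt_x = np.deg2rad(25.0 * np.sin(2.0 * np.pi * i / n_views) + rng.uniform(-8, 8))
        tilt_y = np.deg2rad(25.0 * np.cos(2.0 * np.pi * i / n_views) + rng.uniform(-8, 8))
        roll = np.deg2rad(rng.uniform(-30, 30))
        R = Rotation.from_euler("xyz", [tilt_x, tilt_y, roll]).as_matrix()
        t = -R @ centre + np.array(
            [rng.uniform(-2, 2), rng.uniform(-2, 2), distance_mm + rng.uniform(-5, 5)]
        )
        pose = RigidTransform(R, t, from_frame="board", to_frame=CAMERA)
        pc = pose.transform_points(corners)
        uv = project(intr, dist, pc)
        if noise_sigma_px > 0:
            uv = uv + rng.normal(0.0, noise_sigma_px, size=uv.shape)
        views.append(CalibrationView(corners, uv))
        poses.append(pose)
    return views, poses
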