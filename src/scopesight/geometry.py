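"""SE(3) rigid-transform algebra and point-set registration.

Every other module is built on the types here. Conventions, fixed once for
the whole package:

* column vectors, pre-multiplication: a point ``p`` in the source frame maps
  to ``R @ p + t`` in the destination frame;
* lengths in millimetres, angles in degrees at every public interface
  (radians only inside function bodies);
* transforms carry frame labels and composition checks that they chain, so a
  mis-ordered chain such as camera-to-model composed with sensor-to-marker
  fails loudly instead of silently producing a wrong overlay.

The canonical frames of the navigation chain are exported as module
constants: the tracker sensor ``SENSOR``, the organ-model base plate
``MODEL``, the scope-head marker ``SCOPE_HEAD``, the scope tip ``TIP`` and
the (oblique) camera sight ``CAMERA``.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SENSOR",
    "MODEL",
    "SCOPE_HEAD",
    "TIP",
    "CAMERA",
    "WORLD",
    "FrameMismatchError",
    "DegenerateGeometryError",
    "RigidTransform",
    "PointSet",
    "identity",
    "compose",
    "invert",
    "apply",
    "absolute_orientation",
    "rotation_about_axis",
    "rotation_geodesic_deg",
    "random_rigid_transform",
    "transform_to_dict",
    "transform_from_dict",
    "save_transform",
    "load_transform",
]

SENSOR = "sensor"
MODEL = "model"
SCOPE_HEAD = "scope_head"
TIP = "tip"
CAMERA = "camera"
WORLD = "world"

_ORTHO_ATOL = 1e-9


class FrameMismatchError(ValueError):
    """Raised when transform/point frame labels do not chain."""


class DegenerateGeometryError(ValueError):
    """Raised for point sets too degenerate to define a rigid fit."""


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation mapping points ``from_frame`` -> ``to_frame``.

    ``rotation`` is a proper orthonormal 3x3 matrix (validated on
    construction to 1e-9), ``translation`` a 3-vector in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray
    from_frame: str = WORLD
    to_frame: str = WORLD

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rotation or translation")
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_ATOL):
            raise ValueError("rotation is not orthonormal (RR^T != I at 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_ATOL):
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls, frame: str = WORLD) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), from_frame=frame, to_frame=frame)

    @classmethod
    def from_matrix(
        cls, m: np.ndarray, from_frame: str = WORLD, to_frame: str = WORLD
    ) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (validates orthonormality)."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected 4x4 homogeneous matrix, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last row of homogeneous matrix must be [0,0,0,1]")
        return cls(m[:3, :3], m[:3, 3], from_frame=from_frame, to_frame=to_frame)

    @classmethod
    def from_translation(
        cls, t: Sequence[float], from_frame: str = WORLD, to_frame: str = WORLD
    ) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float), from_frame, to_frame)

    # -- views -------------------------------------------------------------

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix view of the transform."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def with_frames(self, from_frame: str, to_frame: str) -> "RigidTransform":
        """Same geometry, relabelled frames."""
        return RigidTransform(self.rotation, self.translation, from_frame, to_frame)

    def transform_points(self, pts: np.ndarray) -> np.ndarray:
        """Map an (N,3) array of points; no frame checking (see :func:`apply`)."""
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def transform_directions(self, d: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (translation ignored)."""
        return np.asarray(d, dtype=float) @ self.rotation.T

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )

    def __repr__(self) -> str:  # compact, frame-first
        return (
            f"RigidTransform({self.from_frame!r} -> {self.to_frame!r}, "
            f"t={np.array2string(self.translation, precision=3)})"
        )


@dataclasses.dataclass(frozen=True)
class PointSet:
    """Ordered 3D points (mm) tagged with the frame they live in.

    Order is identity-bearing: index i of one set corresponds to index i of
    a paired set (used by the rigid fit and the tracker).
    """

    points: np.ndarray
    frame: str = WORLD

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N,3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


def identity(frame: str = WORLD) -> RigidTransform:
    return RigidTransform.identity(frame)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform that applies ``b`` first, then ``a``.

    Frames must chain: ``b.to_frame == a.from_frame``; the result maps
    ``b.from_frame -> a.to_frame``.
    """
    if b.to_frame != a.from_frame:
        raise FrameMismatchError(
            f"cannot compose: inner transform ends in {b.to_frame!r} "
            f"but outer starts in {a.from_frame!r}"
        )
    return RigidTransform(
        a.rotation @ b.rotation,
        a.rotation @ b.translation + a.translation,
        from_frame=b.from_frame,
        to_frame=a.to_frame,
    )


def compose_all(*transforms: RigidTransform) -> RigidTransform:
    """Left-to-right chain: ``compose_all(a, b, c)`` applies c, then b, then a."""
    if not transforms:
        raise ValueError("need at least one transform")
    out = transforms[-1]
    for t in reversed(transforms[:-1]):
        out = compose(t, out)
    return out


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse transform: ``R' = R^T``, ``t' = -R^T t``, frames swapped."""
    rt = t.rotation.T
    return RigidTransform(rt, -rt @ t.translation, t.to_frame, t.from_frame)


def apply(t: RigidTransform, pts: PointSet) -> PointSet:
    """Map a :class:`PointSet` through ``t``, relabelling its frame."""
    if pts.frame != t.from_frame:
        raise FrameMismatchError(
            f"points are in frame {pts.frame!r} but transform starts "
            f"in {t.from_frame!r}"
        )
    return PointSet(t.transform_points(pts.points), frame=t.to_frame)


def rotation_about_axis(
    axis: Sequence[float],
    angle_deg: float,
    from_frame: str = WORLD,
    to_frame: str | None = None,
) -> RigidTransform:
    """Rodrigues rotation about a unit axis (degrees), zero translation."""
    axis = np.asarray(axis, dtype=float).reshape(3)
    n = np.linalg.norm(axis)
    if abs(n - 1.0) > 1e-9:
        raise ValueError(f"axis must be unit length (|axis| = {n:.3e})")
    th = np.deg2rad(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    R = np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)
    return RigidTransform(
        R, np.zeros(3), from_frame, to_frame if to_frame is not None else from_frame
    )


def absolute_orientation(
    src: PointSet | np.ndarray, dst: PointSet | np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit mapping ``src`` onto ``dst`` (Kabsch/Umeyama).

    Returns the transform minimizing ``sum_i ||dst_i - (R src_i + t)||^2``
    (closed form via SVD, with a reflection guard that flips the smallest
    singular direction when the optimum of the unconstrained problem is a
    reflection) and the RMS residual in mm.

    Correspondence is by index. Requires >= 3 points and a non-collinear
    source set; raises :class:`DegenerateGeometryError` otherwise.
    """
    sp = src.points if isinstance(src, PointSet) else np.asarray(src, dtype=float)
    dp = dst.points if isinstance(dst, PointSet) else np.asarray(dst, dtype=float)
    from_frame = src.frame if isinstance(src, PointSet) else WORLD
    to_frame = dst.frame if isinstance(dst, PointSet) else WORLD
    if sp.shape != dp.shape:
        raise ValueError(f"point sets differ in shape: {sp.shape} vs {dp.shape}")
    n = sp.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 correspondences, got {n}")

    sc = sp.mean(axis=0)
    dc = dp.mean(axis=0)
    s0 = sp - sc
    d0 = dp - dc
    # collinearity: second singular value of the centred source cloud
    sing = np.linalg.svd(s0, compute_uv=False)
    if sing[1] <= 1e-9 * max(sing[0], 1.0):
        raise DegenerateGeometryError("source points are (near-)collinear")

    H = s0.T @ d0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    # re-project onto SO(3) to guarantee the 1e-9 orthonormality invariant
    Ur, _, Vtr = np.linalg.svd(R)
    R = Ur @ np.diag([1.0, 1.0, np.sign(np.linalg.det(Ur @ Vtr))]) @ Vtr
    t = dc - R @ sc
    res = dp - (sp @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return RigidTransform(R, t, from_frame, to_frame), rms


def rotation_geodesic_deg(a: RigidTransform | np.ndarray, b: RigidTransform | np.ndarray) -> float:
    """Geodesic distance between two rotations, in degrees."""
    Ra = a.rotation if isinstance(a, RigidTransform) else np.asarray(a, dtype=float)
    Rb = b.rotation if isinstance(b, RigidTransform) else np.asarray(b, dtype=float)
    c = (np.trace(Ra.T @ Rb) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def random_rigid_transform(
    rng: np.random.Generator,
    max_translation_mm: float = 100.0,
    from_frame: str = WORLD,
    to_frame: str = WORLD,
) -> RigidTransform:
    """Uniformly random rotation (QR of a Gaussian matrix) + bounded translation."""
    A = rng.standard_normal((3, 3))
    Q, Rr = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(Rr)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(Q, t, from_frame, to_frame)


# -- serialization ---------------------------------------------------------


def transform_to_dict(t: RigidTransform) -> dict:
    """JSON-ready dict: row-major 4x4 homogeneous matrix + frame labels."""
    return {
        "from_frame": t.from_frame,
        "to_frame": t.to_frame,
        "matrix": [float(x) for x in t.matrix().ravel()],
    }


def transform_from_dict(d: dict) -> RigidTransform:
    m = np.asarray(d["matrix"], dtype=float).reshape(4, 4)
    return RigidTransform.from_matrix(m, d.get("from_frame", WORLD), d.get("to_frame", WORLD))


def save_transform(t: RigidTransform, path) -> None:
    with open(path, "w") as fh:
        json.dump(transform_to_dict(t), fh, indent=2)


def load_transform(path) -> RigidTransform:
    with open(path) as fh:
        return transform_from_dict(json.load(fh))
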