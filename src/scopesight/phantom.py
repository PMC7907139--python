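"""Synthetic elbow phantom: organ meshes, mounting frame, marker layouts.

Generates at desk scale what the real study segments from CT/MRI and 3D
prints: three long bones meeting at a flexed joint, four thin tubular
nerves running past it, a skin envelope, and a rigid mounting frame — all
in a fixed static arrangement relative to the base-plate marker that
defines the model base frame. Also produces the Xpoint marker layouts for
the base plate, the scope head and the lens cylinder, plus the ground-truth
mounting transforms the simulator needs.

Everything is deterministic under the PhantomSpec seed (the seed jitters nerve
routes and marker placement only within realistic bounds).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import (
    MODEL,
    SCOPE_HEAD,
    TIP,
    RigidTransform,
    rotation_about_axis,
)
from .mesh import OrganModel, TriangleMesh
from .tracker import MarkerTemplate

__all__ = [
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "box_mesh",
    "cylinder_mesh",
    "tube_mesh",
    "disk_mesh",
]


# -- mesh primitives -------------------------------------------------------


def box_mesh(size, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Axis-aligned box of ``size = (sx, sy, sz)`` mm centred at ``center``."""
    sx, sy, sz = (float(s) / 2.0 for s in size)
    c = np.asarray(center, dtype=float)
    corners = np.array(
        [
            [-sx, -sy, -sz],
            [+sx, -sy, -sz],
            [+sx, +sy, -sz],
            [-sx, +sy, -sz],
            [-sx, -sy, +sz],
            [+sx, -sy, +sz],
            [+sx, +sy, +sz],
            [-sx, +sy, +sz],
        ]
    ) + c
    faces = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z-)
            [4, 5, 6], [4, 6, 7],  # top (z+)
            [0, 1, 5], [0, 5, 4],  # y-
            [2, 3, 7], [2, 7, 6],  # y+
            [1, 2, 6], [1, 6, 5],  # x+
            [3, 0, 4], [3, 4, 7],  # x-
        ],
        dtype=np.int64,
    )
    return TriangleMesh(corners, faces)


def _ring(center: np.ndarray, u: np.ndarray, v: np.ndarray, radius: float, n: int) -> np.ndarray:
    ang = 2.0 * np.pi * np.arange(n) / n
    return center + radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def tube_mesh(
    centerline: np.ndarray, radius: float, segments: int = 12, capped: bool = True
) -> TriangleMesh:
    """Sweep a circle of ``radius`` along a polyline using parallel transport.

    Parallel-transport frames avoid the twisting artifacts of a fixed
    reference vector when the curve bends through the vertical.
    """
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("centerline needs >= 2 points")
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # initial normal: anything perpendicular to the first tangent
    t0 = tangents[0]
    helper = np.array([0.0, 0.0, 1.0]) if abs(t0[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(t0, helper)
    u /= np.linalg.norm(u)
    verts = []
    us = []
    for i in range(pts.shape[0]):
        if i > 0:
            # rotate u by the rotation taking tangent[i-1] to tangent[i]
            a, b = tangents[i - 1], tangents[i]
            cross = np.cross(a, b)
            s = np.linalg.norm(cross)
            if s > 1e-12:
                axis = cross / s
                ang = np.degrees(np.arctan2(s, np.clip(np.dot(a, b), -1.0, 1.0)))
                u = rotation_about_axis(axis, ang).rotation @ u
                u -= np.dot(u, tangents[i]) * tangents[i]
                u /= np.linalg.norm(u)
        us.append(u.copy())
        v = np.cross(tangents[i], u)
        verts.append(_ring(pts[i], u, v, radius, segments))
    rings = np.asarray(verts)  # (P, segments, 3)
    P = rings.shape[0]
    vertices = rings.reshape(-1, 3)
    faces = []
    for i in range(P - 1):
        for j in range(segments):
            a = i * segments + j
            b = i * segments + (j + 1) % segments
            c = (i + 1) * segments + j
            d = (i + 1) * segments + (j + 1) % segments
            faces.append([a, b, d])
            faces.append([a, d, c])
    if capped:
        start_c = len(vertices)
        vertices = np.vstack([vertices, pts[0], pts[-1]])
        for j in range(segments):
            faces.append([start_c, (j + 1) % segments, j])
            base = (P - 1) * segments
            faces.append([start_c + 1, base + j, base + (j + 1) % segments])
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))


def cylinder_mesh(
    radius: float, length: float, segments: int = 24, axis_samples: int = 2
) -> TriangleMesh:
    """Capped circular cylinder along +z, base at the origin."""
    z = np.linspace(0.0, length, max(axis_samples, 2))
    centerline = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    return tube_mesh(centerline, radius, segments, capped=True)


def disk_mesh(radius: float, segments: int = 32) -> TriangleMesh:
    """Flat disk in the z=0 plane centred at the origin (the circular target)."""
    ang = 2.0 * np.pi * np.arange(segments) / segments
    rim = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(segments)])
    vertices = np.vstack([[0.0, 0.0, 0.0], rim])
    faces = np.array(
        [[0, 1 + j, 1 + (j + 1) % segments] for j in range(segments)], dtype=np.int64
    )
    return TriangleMesh(vertices, faces)


# -- marker layouts --------------------------------------------------------


def _marker_layout(extent_mm: float, jitter_mm: float, rng: np.random.Generator) -> np.ndarray:
    """Five Xpoints: four corners of a square + one out-of-plane point.

    The out-of-plane point breaks planarity symmetric ambiguities and gives
    every tool a distinct inter-point distance signature once jittered.
    """
    h = extent_mm / 2.0
    base = np.array(
        [
            [-h, -h, 0.0],
            [+h, -h, 0.0],
            [+h, +h, 0.0],
            [-h, +h, 0.0],
            [0.0, 0.0, extent_mm / 4.0],
        ]
    )
    return base + rng.uniform(-jitter_mm, jitter_mm, size=base.shape)


# -- phantom spec ----------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom (all lengths in mm)."""

    seed: int = 0
    humerus_radius: float = 12.0
    forearm_bone_radius: float = 7.0
    bone_length: float = 120.0
    nerve_radius: float = 1.5
    skin_radius: float = 45.0
    frame_size: tuple[float, float, float] = (160.0, 100.0, 12.0)
    base_marker_extent: float = 70.0
    head_marker_extent: float = 70.0
    cylinder_marker_extent: float = 40.0
    marker_jitter: float = 2.0
    tube_segments: int = 12
    cylinder_segments: int = 24

    def __post_init__(self):
        for field in (
            "humerus_radius",
            "forearm_bone_radius",
            "bone_length",
            "nerve_radius",
            "skin_radius",
            "base_marker_extent",
            "head_marker_extent",
            "cylinder_marker_extent",
        ):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if any(s <= 0 for s in self.frame_size):
            raise ValueError("frame dimensions must be positive")


@dataclasses.dataclass(frozen=True)
class Phantom:
    """Generated phantom: organs, marker templates, ground-truth mounts."""

    organs: tuple[OrganModel, ...]
    templates: dict  # name -> MarkerTemplate
    # ground truth the simulator needs: scope-head -> tip mount, and the
    # lens-cylinder marker's pose in the head frame at theta = 0
    T_AT: RigidTransform
    T_A_cyl0: RigidTransform
    # nerve centreline curves (model base frame, mm): generation ground
    # truth kept for geometric validation of the tube meshes
    nerve_centerlines: dict = dataclasses.field(default_factory=dict)

    def organ(self, name: str) -> OrganModel:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)


def _nerve_curve(
    start: np.ndarray, mid: np.ndarray, end: np.ndarray, n: int = 25
) -> np.ndarray:
    """Quadratic Bezier through three control points: a smooth 3D route."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * start + 2 * (1 - t) * t * mid + t**2 * end


def _organ(name: str, mesh: TriangleMesh, anchor: np.ndarray | None = None) -> OrganModel:
    """Store the mesh organ-locally, anchored at its reference point.

    The default reference point is the mesh centroid, giving each organ a
    non-trivial static placement ``T_MO`` in the model base frame.
    """
    if anchor is None:
        anchor = mesh.vertices.mean(axis=0)
    local = TriangleMesh(mesh.vertices - anchor, mesh.faces)
    # T_MO maps model-base coords to organ-local coords: subtract the anchor
    T_MO = RigidTransform(np.eye(3), -anchor, MODEL, name)
    return OrganModel(name, local, T_MO)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the full synthetic phantom from a spec, deterministically.

    Layout (model base frame, mm): the joint centre sits at the origin; the
    humerus runs up +z, the radius and ulna run out along +x (the elbow is
    held flexed at 90 degrees, as the physical model is printed), nerves
    pass close to the joint on smooth curves, and the frame block sits
    below everything. The base-plate marker IS the model base frame: its
    Xpoints are expressed directly in it.
    """
    rng = np.random.default_rng(spec.seed)
    joint = np.zeros(3)
    organs: list[OrganModel] = []

    # bones: capped cylinders.  humerus along +z, radius/ulna along +x.
    humerus = cylinder_mesh(spec.humerus_radius, spec.bone_length, spec.cylinder_segments)
    organs.append(_organ("humerus", humerus))

    def forearm(offset_y: float, name: str) -> OrganModel:
        m = cylinder_mesh(spec.forearm_bone_radius, spec.bone_length, spec.cylinder_segments)
        # rotate +z onto +x, then shift sideways
        R = rotation_about_axis((0.0, 1.0, 0.0), 90.0).rotation
        v = m.vertices @ R.T + np.array([spec.humerus_radius, offset_y, 0.0])
        return _organ(name, TriangleMesh(v, m.faces))

    organs.append(forearm(-spec.forearm_bone_radius - 1.0, "radius"))
    organs.append(forearm(+spec.forearm_bone_radius + 1.0, "ulna"))

    # nerves: thin tubes on smooth curves passing near the joint, jittered
    nerve_routes = {
        "radial nerve": (np.array([-20.0, -25.0, 90.0]), np.array([18.0, -20.0, 5.0]),
                         np.array([95.0, -18.0, -8.0])),
        "ulnar nerve": (np.array([-18.0, 25.0, 90.0]), np.array([12.0, 24.0, -4.0]),
                        np.array([95.0, 20.0, -6.0])),
        "median nerve": (np.array([-25.0, 5.0, 90.0]), np.array([20.0, 8.0, 12.0]),
                         np.array([95.0, 6.0, 10.0])),
        "musculocutaneous nerve": (np.array([-30.0, -8.0, 85.0]), np.array([15.0, -6.0, 22.0]),
                                   np.array([85.0, -10.0, 25.0])),
    }
    centerlines: dict = {}
    for name, (a, b, c) in nerve_routes.items():
        jit = rng.uniform(-3.0, 3.0, size=3)
        curve = _nerve_curve(a, b + jit, c)
        centerlines[name] = curve
        organs.append(_organ(name, tube_mesh(curve, spec.nerve_radius, spec.tube_segments)))

    # skin: wide tube around the forearm axis (a stylized envelope)
    skin_line = np.column_stack(
        [np.linspace(-10.0, 110.0, 13), np.zeros(13), np.zeros(13)]
    )
    organs.append(_organ("skin", tube_mesh(skin_line, spec.skin_radius, 24)))

    # mounting frame block beneath the anatomy
    frame_center = np.array([40.0, 0.0, -spec.skin_radius - spec.frame_size[2] / 2.0 - 5.0])
    organs.append(_organ("frame", box_mesh(spec.frame_size, frame_center)))

    for o in organs:
        o.mesh.validate()

    templates = {
        "base_plate": MarkerTemplate(
            "base_plate", _marker_layout(spec.base_marker_extent, spec.marker_jitter, rng)
        ),
        "scope_head": MarkerTemplate(
            "scope_head", _marker_layout(spec.head_marker_extent, spec.marker_jitter, rng)
        ),
        "lens_cylinder": MarkerTemplate(
            "lens_cylinder", _marker_layout(spec.cylinder_marker_extent, spec.marker_jitter, rng)
        ),
    }

    # scope-head marker -> tip: the marker sits on the camera head, the tip
    # is ~180 mm down the shaft (+z in both frames here)
    T_AT = RigidTransform(
        np.eye(3), np.array([0.0, -20.0, -180.0]), SCOPE_HEAD, TIP
    )
    # lens-cylinder marker mount in the head frame at theta = 0
    T_A_cyl0 = RigidTransform(
        rotation_about_axis((0.0, 0.0, 1.0), 15.0).rotation,
        np.array([0.0, 25.0, 60.0]),
        "lens_cylinder",
        SCOPE_HEAD,
    )
    return Phantom(tuple(organs), templates, T_AT, T_A_cyl0, centerlines)
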