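"""Triangle meshes, STL reading/writing, and organ-model bookkeeping.

Organ surfaces travel as STL (both the ASCII dialect and little-endian
binary), the format the segmented anatomy is exported in. The reader welds
exactly-equal vertices (no epsilon merging, so welding is deterministic and
reversible); the binary writer is byte-deterministic for a given mesh and
writes the attribute byte count as 0. Units are millimetres by convention —
STL itself carries no unit metadata.
"""

from __future__ import annotations

import dataclasses
import io
import json
import struct
from typing import BinaryIO

import numpy as np

from .geometry import MODEL, RigidTransform, invert

__all__ = [
    "TriangleMesh",
    "OrganModel",
    "ORGAN_NAMES",
    "STLFormatError",
    "read_stl",
    "write_stl",
    "transform_mesh",
    "save_organ_set",
    "load_organ_set",
]

ORGAN_NAMES = frozenset(
    {
        "skin",
        "radius",
        "ulna",
        "humerus",
        "radial nerve",
        "ulnar nerve",
        "median nerve",
        "musculocutaneous nerve",
        "frame",
        "circle target",
    }
)


class STLFormatError(ValueError):
    """Malformed or truncated STL data; message carries a byte/line offset."""


@dataclasses.dataclass(frozen=True)
class TriangleMesh:
    """Indexed triangle mesh: vertices (N,3) mm, faces (M,3) vertex indices."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (N,3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (M,3), got {f.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite vertex coordinates")
        if f.size and (f.min() < 0 or f.max() >= v.shape[0]):
            raise ValueError("face indices out of range")
        v.setflags(write=False)
        f.setflags(write=False)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def triangles(self) -> np.ndarray:
        """(M,3,3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        """Unit normals from vertex winding (right-hand rule); zero for degenerate."""
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            unit = np.where(norm > 0, n / np.where(norm == 0, 1.0, norm), 0.0)
        return unit

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def surface_area(self) -> float:
        return float(self.face_areas().sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as (E,2) sorted index pairs."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def validate(self) -> None:
        """Raise if any face has zero area (generation-time invariant)."""
        if self.n_faces and np.any(self.face_areas() <= 0.0):
            bad = np.nonzero(self.face_areas() <= 0.0)[0]
            raise ValueError(f"degenerate (zero-area) faces at indices {bad.tolist()}")


def transform_mesh(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Rigidly move a mesh; topology unchanged, areas/edge lengths preserved."""
    return TriangleMesh(t.transform_points(mesh.vertices), mesh.faces)


# -- STL -------------------------------------------------------------------

_BINARY_HEADER = b"scopesight binary STL".ljust(80, b"\x00")


def _weld(tri_vertices: np.ndarray) -> TriangleMesh:
    """Index a triangle soup by exact (bitwise float) vertex equality."""
    flat = np.ascontiguousarray(tri_vertices.reshape(-1, 3))
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriangleMesh(uniq, faces)


def read_stl(source: BinaryIO | bytes | str) -> TriangleMesh:
    """Read ASCII or little-endian binary STL; vertices exactly welded.

    ``source`` may be a path, raw bytes, or a binary stream. Malformed
    records raise :class:`STLFormatError` with the offending line (ASCII)
    or byte offset (binary).
    """
    if isinstance(source, (str,)):
        with open(source, "rb") as fh:
            data = fh.read()
    elif isinstance(source, bytes):
        data = source
    else:
        data = source.read()
    if len(data) < 15:
        raise STLFormatError(f"file too short to be STL ({len(data)} bytes)")
    # An ASCII file starts with "solid"; but so may a binary header. Decide
    # by record arithmetic: a well-formed binary file's length matches its
    # triangle-count field.
    if data[:5] == b"solid":
        if len(data) >= 84:
            (count,) = struct.unpack_from("<I", data, 80)
            if len(data) == 84 + 50 * count:
                return _read_binary(data)
        return _read_ascii(data)
    return _read_binary(data)


def _read_binary(data: bytes) -> TriangleMesh:
    if len(data) < 84:
        raise STLFormatError(
            f"truncated binary STL: {len(data)} bytes, header needs 84"
        )
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) < expected:
        got = (len(data) - 84) // 50
        raise STLFormatError(
            f"truncated binary STL: count field says {count} triangles "
            f"but only {got} complete records present (byte {len(data)} of {expected})"
        )
    if len(data) > expected:
        raise STLFormatError(
            f"binary STL has {len(data) - expected} trailing bytes after "
            f"{count} records (byte {expected})"
        )
    rec = np.frombuffer(data, dtype=np.uint8, count=50 * count, offset=84)
    rec = rec.reshape(count, 50)
    floats = rec[:, :48].copy().view("<f4").reshape(count, 4, 3).astype(float)
    tris = floats[:, 1:4, :]  # drop the stored normal; recomputed on demand
    return _weld(tris)


def _read_ascii(data: bytes) -> TriangleMesh:
    try:
        text = data.decode("ascii")
    except UnicodeDecodeError as exc:
        raise STLFormatError(f"ASCII STL contains non-ASCII byte at {exc.start}") from exc
    tris: list[list[list[float]]] = []
    current: list[list[float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        kw = tokens[0]
        if kw == "vertex":
            if len(tokens) != 4:
                raise STLFormatError(f"line {lineno}: vertex needs 3 coordinates")
            try:
                current.append([float(x) for x in tokens[1:4]])
            except ValueError:
                raise STLFormatError(f"line {lineno}: non-numeric vertex coordinate")
        elif kw == "endloop":
            if len(current) != 3:
                raise STLFormatError(
                    f"line {lineno}: facet loop has {len(current)} vertices, expected 3"
                )
            tris.append(current)
            current = []
        elif kw in ("solid", "endsolid", "facet", "endfacet", "outer"):
            continue
        else:
            raise STLFormatError(f"line {lineno}: unexpected token {kw!r}")
    if current:
        raise STLFormatError("unterminated facet loop at end of file")
    if not tris:
        return TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    # STL is a float32 format: snap parsed ASCII values to float32 so the
    # two dialects of the same mesh weld to identical vertices
    return _weld(np.asarray(tris, dtype=np.float32).astype(float))


def write_stl(mesh: TriangleMesh, dialect: str = "binary") -> bytes:
    """Serialize a mesh to STL bytes (``"binary"`` or ``"ascii"``).

    Normals are recomputed from vertex winding; binary output is
    byte-deterministic (fixed header, attribute count 0).
    """
    if mesh.n_faces == 0:
        raise ValueError("refusing to write an empty mesh")
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    tri = mesh.triangles().astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    if dialect == "binary":
        out = io.BytesIO()
        out.write(_BINARY_HEADER)
        out.write(struct.pack("<I", mesh.n_faces))
        rec = np.zeros((mesh.n_faces, 50), dtype=np.uint8)
        block = np.concatenate([normals[:, None, :], tri], axis=1)  # (M,4,3) f32
        flat = np.ascontiguousarray(block.reshape(mesh.n_faces, 12), dtype="<f4")
        rec[:, :48] = flat.view(np.uint8).reshape(mesh.n_faces, 48)
        out.write(rec.tobytes())
        return out.getvalue()
    lines = ["solid scopesight"]
    for i in range(mesh.n_faces):
        n = normals[i]
        lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
        lines.append("    outer loop")
        for v in tri[i]:
            lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid scopesight")
    return ("\n".join(lines) + "\n").encode("ascii")


def write_stl_file(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    with open(path, "wb") as fh:
        fh.write(write_stl(mesh, dialect))


# -- organ models ----------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class OrganModel:
    """Named organ mesh with its static placement in the model base frame.

    The mesh lives in the organ's local frame; ``T_MO`` maps model-base
    coordinates to organ-local coordinates (so placement into the base
    frame uses its inverse). The spatial arrangement is static for a
    session — the anatomy and frame are rigidly mounted together.
    """

    name: str
    mesh: TriangleMesh
    T_MO: RigidTransform

    def __post_init__(self):
        if self.name not in ORGAN_NAMES:
            raise ValueError(
                f"unknown organ name {self.name!r}; expected one of {sorted(ORGAN_NAMES)}"
            )
        if self.T_MO.from_frame != MODEL:
            raise ValueError("T_MO must map the model base frame to the organ")

    def mesh_in_model_frame(self) -> TriangleMesh:
        return transform_mesh(self.mesh, invert(self.T_MO))


def save_organ_set(organs, directory, manifest_name: str = "organs.json") -> None:
    """Write each organ as binary STL plus a JSON manifest (name, path, T_MO)."""
    import os

    entries = []
    for o in organs:
        fname = o.name.replace(" ", "_") + ".stl"
        write_stl_file(o.mesh, os.path.join(directory, fname), "binary")
        entries.append(
            {
                "name": o.name,
                "stl": fname,
                "T_MO": [float(x) for x in o.T_MO.matrix().ravel()],
            }
        )
    with open(os.path.join(directory, manifest_name), "w") as fh:
        json.dump(entries, fh, indent=2)


def load_organ_set(directory, manifest_name: str = "organs.json") -> list[OrganModel]:
    import os

    with open(os.path.join(directory, manifest_name)) as fh:
        entries = json.load(fh)
    organs = []
    for e in entries:
        mesh = read_stl(os.path.join(directory, e["stl"]))
        T_MO = RigidTransform.from_matrix(
            np.asarray(e["T_MO"], dtype=float).reshape(4, 4), MODEL, e["name"]
        )
        organs.append(OrganModel(e["name"], mesh, T_MO))
    return organs
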