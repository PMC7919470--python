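"""STL (binary and ASCII) and PLY (ASCII) mesh readers/writers.

STL stores a triangle soup, so reading welds exactly-coincident vertices
back together; round trips preserve geometry to float precision.  Units
are always millimetres.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from ..mesh import SurfaceMesh

__all__ = ["read_mesh", "write_mesh", "MeshParseError"]


class MeshParseError(ValueError):
    """Malformed mesh file; message carries the byte offset where known."""


_STL_DTYPE = np.dtype([
    ("normal", "<f4", (3,)),
    ("v", "<f4", (3, 3)),
    ("attr", "<u2"),
])


def _weld(tri_verts: np.ndarray, label: str | None) -> SurfaceMesh:
    flat = tri_verts.reshape(-1, 3)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    return SurfaceMesh(uniq, inv.reshape(-1, 3), label)


# ----------------------------------------------------------------------
# STL
# ----------------------------------------------------------------------

def _read_stl(path: Path, label: str | None) -> SurfaceMesh:
    data = path.read_bytes()
    if len(data) < 15:
        raise MeshParseError(f"{path}: file too short ({len(data)} bytes) at offset 0")
    is_ascii = data[:5] == b"solid" and b"facet" in data[:500]
    if is_ascii:
        return _read_stl_ascii(data, path, label)
    if len(data) < 84:
        raise MeshParseError(f"{path}: truncated binary STL header at offset {len(data)}")
    (n,) = struct.unpack("<I", data[80:84])
    need = 84 + n * 50
    if len(data) < need:
        raise MeshParseError(
            f"{path}: binary STL declares {n} triangles but ends at offset {len(data)} (need {need})")
    rec = np.frombuffer(data, dtype=_STL_DTYPE, count=n, offset=84)
    return _weld(rec["v"].astype(np.float64), label)


def _read_stl_ascii(data: bytes, path: Path, label: str | None) -> SurfaceMesh:
    tris = []
    cur: list[list[float]] = []
    offset = 0
    for line in data.splitlines():
        stripped = line.strip()
        if stripped.startswith(b"vertex"):
            parts = stripped.split()
            if len(parts) != 4:
                raise MeshParseError(f"{path}: bad vertex line at offset {offset}")
            try:
                cur.append([float(x) for x in parts[1:]])
            except ValueError as e:
                raise MeshParseError(f"{path}: unparsable vertex at offset {offset}: {e}") from e
        elif stripped.startswith(b"endfacet"):
            if len(cur) != 3:
                raise MeshParseError(f"{path}: facet with {len(cur)} vertices at offset {offset}")
            tris.append(cur)
            cur = []
        offset += len(line) + 1
    if cur:
        raise MeshParseError(f"{path}: unterminated facet at offset {offset}")
    if not tris:
        raise MeshParseError(f"{path}: ASCII STL contains no facets at offset {offset}")
    return _weld(np.array(tris, dtype=np.float64), label)


def _write_stl(mesh: SurfaceMesh, path: Path, binary: bool) -> None:
    t = mesh.triangles().astype(np.float32)
    n = mesh.face_normals().astype(np.float32)
    if binary:
        rec = np.zeros(len(t), dtype=_STL_DTYPE)
        rec["normal"] = n
        rec["v"] = t
        with open(path, "wb") as fh:
            fh.write(b"arguide binary STL".ljust(80, b" "))
            fh.write(struct.pack("<I", len(t)))
            fh.write(rec.tobytes())
    else:
        name = mesh.label or "mesh"
        with open(path, "w") as fh:
            fh.write(f"solid {name}\n")
            for ni, ti in zip(n, t):
                fh.write(f"  facet normal {ni[0]:.9g} {ni[1]:.9g} {ni[2]:.9g}\n    outer loop\n")
                for v in ti:
                    fh.write(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                fh.write("    endloop\n  endfacet\n")
            fh.write(f"endsolid {name}\n")


# ----------------------------------------------------------------------
# PLY (ASCII)
# ----------------------------------------------------------------------

def _read_ply(path: Path, label: str | None) -> SurfaceMesh:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise MeshParseError(f"{path}: not a PLY file at offset 0")
        n_vert = n_face = 0
        fmt = None
        while True:
            line = fh.readline()
            if not line:
                raise MeshParseError(f"{path}: header ends without end_header at offset {fh.tell()}")
            tok = line.split()
            if not tok:
                continue
            if tok[0] == b"format":
                fmt = tok[1]
            elif tok[0] == b"element":
                if tok[1] == b"vertex":
                    n_vert = int(tok[2])
                elif tok[1] == b"face":
                    n_face = int(tok[2])
            elif tok[0] == b"end_header":
                break
        if fmt != b"ascii":
            raise MeshParseError(f"{path}: only ASCII PLY is supported (got {fmt!r})")
        verts = np.empty((n_vert, 3))
        for i in range(n_vert):
            line = fh.readline()
            if not line:
                raise MeshParseError(f"{path}: truncated vertex list at offset {fh.tell()}")
            verts[i] = [float(x) for x in line.split()[:3]]
        faces = []
        for i in range(n_face):
            line = fh.readline()
            if not line:
                raise MeshParseError(f"{path}: truncated face list at offset {fh.tell()}")
            vals = [int(x) for x in line.split()]
            if vals[0] != 3:
                raise MeshParseError(f"{path}: non-triangular face (n={vals[0]}) at offset {fh.tell()}")
            faces.append(vals[1:4])
    return SurfaceMesh(verts, np.array(faces, dtype=np.int64), label)


def _write_ply(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment arguide mesh, units mm\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_faces}\nproperty list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


# ----------------------------------------------------------------------
# dispatch
# ----------------------------------------------------------------------

def read_mesh(path, label: str | None = None) -> SurfaceMesh:
    """Read an STL (binary or ASCII) or PLY (ASCII) mesh, mm units."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        return _read_stl(path, label)
    if suffix == ".ply":
        return _read_ply(path, label)
    raise ValueError(f"unsupported mesh format: {path.name}")


def write_mesh(mesh: SurfaceMesh, path, binary: bool = True) -> None:
    """Write STL (binary by default, ``binary=False`` for ASCII) or PLY."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".stl":
        _write_stl(mesh, path, binary)
    elif suffix == ".ply":
        _write_ply(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format: {path.name}")
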