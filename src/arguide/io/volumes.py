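"""Volume readers/writers: NRRD (minimal dialect) and NIfTI-1.

NIfTI goes through nibabel and is reoriented to RAS on read.  NRRD is a
small hand-rolled implementation covering the common 3D scalar case
(raw or gzip encoding, ``space directions`` as an axis-aligned or
general 3x3 matrix whose row norms give the spacing); LPS-flagged files
are converted to RAS with a warning.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from ..imaging import LabelMask, VolumeImage

__all__ = ["read_volume", "write_volume"]

log = logging.getLogger(__name__)

_NRRD_TYPES = {
    "signed char": np.int8, "int8": np.int8, "uchar": np.uint8, "uint8": np.uint8,
    "short": np.int16, "int16": np.int16, "ushort": np.uint16, "uint16": np.uint16,
    "int": np.int32, "int32": np.int32, "uint": np.uint32, "uint32": np.uint32,
    "float": np.float32, "double": np.float64,
}
_NRRD_NAMES = {np.dtype(v): k for k, v in _NRRD_TYPES.items()}


def _parse_vector_list(s: str) -> np.ndarray:
    vecs = []
    for part in s.replace(") (", ")|(").replace(" (", "|(").split("|"):
        part = part.strip().strip("()")
        if part.lower() == "none" or not part:
            continue
        vecs.append([float(x) for x in part.replace(",", " ").split()])
    return np.array(vecs)


def _read_nrrd(path: Path) -> VolumeImage:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        header: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").strip()
            if text.startswith("#"):
                continue
            key, _, value = text.partition(":")
            header[key.strip().lower()] = value.lstrip("= ").strip()
        payload = fh.read()

    if int(header.get("dimension", "3")) != 3:
        raise ValueError(f"{path}: only 3D NRRD volumes are supported")
    dtype = _NRRD_TYPES[header["type"]]
    shape = tuple(int(x) for x in header["sizes"].split())
    enc = header.get("encoding", "raw")
    if enc in ("gzip", "gz"):
        payload = gzip.decompress(payload)
    elif enc != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {enc!r}")
    endian = header.get("endian", "little")
    dt = np.dtype(dtype).newbyteorder("<" if endian == "little" else ">")
    vox = np.frombuffer(payload, dtype=dt, count=int(np.prod(shape)))
    # NRRD is fastest-axis-first; store index order (i, j, k)
    vox = vox.reshape(shape[::-1]).transpose(2, 1, 0)

    spacing = np.ones(3)
    if "space directions" in header:
        dirs = _parse_vector_list(header["space directions"])
        spacing = np.linalg.norm(dirs, axis=1)
    elif "spacings" in header:
        spacing = np.array([float(x) for x in header["spacings"].split()])
    origin = np.zeros(3)
    if "space origin" in header:
        origin = _parse_vector_list(header["space origin"]).ravel()

    space = header.get("space", "right-anterior-superior").lower()
    if space.startswith("left-posterior") or space == "lps":
        log.warning("%s: LPS-oriented NRRD converted to RAS (x, y negated)", path)
        origin = origin * np.array([-1.0, -1.0, 1.0])
    return VolumeImage(np.ascontiguousarray(vox), spacing, origin)


def _write_nrrd(vol: VolumeImage, path: Path, encoding: str = "gzip") -> None:
    arr = np.ascontiguousarray(vol.voxels.transpose(2, 1, 0))
    dt = np.dtype(arr.dtype)
    if dt not in _NRRD_NAMES:
        arr = arr.astype(np.float32)
        dt = np.dtype(np.float32)
    payload = arr.astype(dt.newbyteorder("<")).tobytes()
    if encoding == "gzip":
        payload = gzip.compress(payload, mtime=0)
    sx, sy, sz = vol.spacing
    ox, oy, oz = vol.origin
    header = (
        "NRRD0004\n"
        f"type: {_NRRD_NAMES[dt]}\n"
        "dimension: 3\n"
        "space: right-anterior-superior\n"
        f"sizes: {vol.shape[0]} {vol.shape[1]} {vol.shape[2]}\n"
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        f"encoding: {encoding}\n"
        f"space origin: ({ox},{oy},{oz})\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


def _read_nifti(path: Path) -> VolumeImage:
    img = nib.as_closest_canonical(nib.load(str(path)))  # reorient to RAS
    aff = img.affine
    spacing = np.linalg.norm(aff[:3, :3], axis=0)
    origin = aff[:3, 3]
    return VolumeImage(np.asarray(img.dataobj), spacing, origin)


def _write_nifti(vol: VolumeImage, path: Path) -> None:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.spacing)
    aff[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(np.asarray(vol.voxels), aff), str(path))


def read_volume(path, as_mask: bool = False, label: str = "label") -> VolumeImage:
    """Read NRRD or NIfTI into RAS mm; ``as_mask`` binarizes (> 0)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".nrrd"):
        vol = _read_nrrd(path)
    elif name.endswith((".nii", ".nii.gz")):
        vol = _read_nifti(path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if as_mask:
        return LabelMask((np.asarray(vol.voxels) > 0).astype(np.uint8),
                         vol.spacing, vol.origin, label=label)
    return vol


def write_volume(vol: VolumeImage, path) -> None:
    """Write NRRD (gzip) or NIfTI-1 according to the file extension."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".nrrd"):
        _write_nrrd(vol, path)
    elif name.endswith((".nii", ".nii.gz")):
        _write_nifti(vol, path)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
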