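"""3D Slicer markups fiducial (FCSV) reader/writer, RAS millimetres.

The dialect is the comma-separated markups format: comment header lines
declaring version and coordinate system, then one row per point with
``id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID``.
LPS-flagged files are converted to RAS (x and y negated) with a warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from ..registration import FiducialSet

__all__ = ["read_fcsv", "write_fcsv"]

log = logging.getLogger(__name__)


def read_fcsv(path, frame: str = "anatomy") -> FiducialSet:
    path = Path(path)
    coordinate_system = "RAS"
    pts, labels = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                low = line.lower().replace(" ", "")
                if "coordinatesystem" in low:
                    val = low.split("=")[-1]
                    coordinate_system = {"0": "LPS", "1": "RAS", "lps": "LPS", "ras": "RAS"}.get(val, "RAS")
                continue
            parts = line.split(",")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected at least id,x,y,z columns")
            pts.append([float(parts[1]), float(parts[2]), float(parts[3])])
            labels.append(parts[11] if len(parts) > 11 and parts[11] else parts[0])
    pts = np.array(pts, dtype=float).reshape(-1, 3)
    if coordinate_system == "LPS":
        log.warning("%s: LPS fiducials converted to RAS (x, y negated)", path)
        pts[:, 0] *= -1.0
        pts[:, 1] *= -1.0
    return FiducialSet(pts, labels, frame)


def write_fcsv(fiducials: FiducialSet, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write("# CoordinateSystem = RAS\n")
        fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
        for i, (p, lab) in enumerate(zip(fiducials.points, fiducials.labels), 1):
            fh.write(f"vtkMRMLMarkupsFiducialNode_{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},"
                     f"0,0,0,1,1,1,0,{lab},,\n")
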