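"""Cubic AR reference marker: geometry and a noisy tracking stand-in.

The physical reference is a 30 mm cube carrying a distinct black-and-white
pattern on each face; a phone camera estimates its 6-DoF pose from any
visible face.  Image-based detection itself is out of scope — tracking is
modeled as the true pose perturbed by small isotropic Gaussian noise,
which is the quantity that actually propagates into navigation error.

Marker frame convention: origin at the cube centre, +z through the face
that mounts onto the guide's holder adaptor (face 5 below is -z, the
mounted face; its pattern is never visible once seated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .registration import FiducialSet
from .transforms import RigidTransform, rotation_from_axis_angle

__all__ = ["MarkerModel", "PoseObservation", "cube_corners", "visible_faces",
           "simulate_marker_observation", "FACE_NORMALS"]

#: face id -> outward unit normal in the marker frame
FACE_NORMALS: dict[int, np.ndarray] = {
    1: np.array([1.0, 0.0, 0.0]),
    2: np.array([-1.0, 0.0, 0.0]),
    3: np.array([0.0, 1.0, 0.0]),
    4: np.array([0.0, -1.0, 0.0]),
    5: np.array([0.0, 0.0, -1.0]),  # mounted to the holder adaptor
    6: np.array([0.0, 0.0, 1.0]),
}


@dataclass
class MarkerModel:
    """Cubic marker with per-face binary patterns (for printing/documentation)."""

    edge_mm: float = 30.0
    pattern_seed: int = 0
    pattern_size: int = 8

    def __post_init__(self) -> None:
        if self.edge_mm <= 0:
            raise ValueError("edge length must be positive")

    def corners(self) -> np.ndarray:
        h = self.edge_mm / 2.0
        return np.array(list(product((-h, h), repeat=3)))

    def face_pattern(self, face_id: int) -> np.ndarray:
        """Deterministic binary pattern bitmap for one face.

        The patterns only need to be unique per face and asymmetric; they
        are generated from a seeded RNG stream, one stream per face.
        """
        if face_id not in FACE_NORMALS:
            raise ValueError(f"face id must be 1..6, got {face_id}")
        rng = np.random.default_rng([self.pattern_seed, face_id])
        return (rng.random((self.pattern_size, self.pattern_size)) > 0.5).astype(np.uint8)

    def to_dict(self) -> dict:
        return {"edge_mm": float(self.edge_mm), "holder_face": 5,
                "pattern_seed": int(self.pattern_seed), "pattern_size": int(self.pattern_size)}


@dataclass
class PoseObservation:
    """One simulated tracking sample of the marker."""

    pose: RigidTransform  # T_camera<-marker (or T_world<-marker)
    timestamp: float = 0.0
    visible: frozenset = field(default_factory=frozenset)
    noise: tuple[float, float] = (0.0, 0.0)  # (sigma_trans mm, sigma_rot deg)


def cube_corners(model: MarkerModel, frame: str = "marker") -> FiducialSet:
    """The 8 cube corners as a labeled fiducial set in the marker frame.

    Labels encode the corner octant, e.g. ``C+-+``.
    """
    pts = model.corners()
    labels = ["C" + "".join("+" if v > 0 else "-" for v in p) for p in pts]
    return FiducialSet(pts, labels, frame)


def visible_faces(pose: RigidTransform, view_direction: np.ndarray,
                  occluded: set[int] | frozenset[int] = frozenset()) -> frozenset[int]:
    """Faces whose outward normal faces the camera, minus occlusions.

    ``view_direction`` is the camera viewing direction (from camera toward
    the marker) in the pose's parent frame; a face is visible when its
    world-frame outward normal has negative dot product with it.
    """
    v = np.asarray(view_direction, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("view direction must be non-zero")
    v = v / n
    out = set()
    for fid, normal in FACE_NORMALS.items():
        if fid in occluded:
            continue
        if (pose.rotation @ normal) @ v < 0:
            out.add(fid)
    return frozenset(out)


def simulate_marker_observation(true_pose: RigidTransform,
                                noise: tuple[float, float] = (0.0, 0.0),
                                seed: int | np.random.Generator = 0,
                                view_direction: np.ndarray | None = None,
                                occluded: frozenset[int] = frozenset(),
                                timestamp: float = 0.0) -> PoseObservation:
    """Perturb the true marker pose by a small random rigid motion.

    Translation: independent N(0, sigma_trans^2) per axis (mm).  Rotation:
    axis uniform on the sphere, angle |N(0, sigma_rot^2)| (degrees) — an
    isotropic small-angle model.  Deterministic for a given seed.
    """
    s_trans, s_rot = noise
    if s_trans < 0 or s_rot < 0:
        raise ValueError("noise standard deviations must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = rng.normal(0.0, s_trans, 3) if s_trans > 0 else np.zeros(3)
    if s_rot > 0:
        axis = rng.standard_normal(3)
        while np.linalg.norm(axis) < 1e-12:
            axis = rng.standard_normal(3)
        ang = abs(rng.normal(0.0, np.radians(s_rot)))
        dR = rotation_from_axis_angle(axis, ang)
    else:
        dR = np.eye(3)
    observed = RigidTransform(true_pose.rotation @ dR, true_pose.translation + dt,
                              true_pose.parent, true_pose.child)
    vis = frozenset()
    if view_direction is not None:
        vis = visible_faces(true_pose, view_direction, occluded)
    return PoseObservation(pose=observed, timestamp=timestamp, visible=vis,
                           noise=(float(s_trans), float(s_rot)))
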