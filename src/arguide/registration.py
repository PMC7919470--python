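"""Point-based rigid registration and the marker -> guide -> anatomy chain.

The navigation concept is classical fiducial registration: two sets of
corresponding landmarks (here, conical holes) related by an unknown rigid
motion.  The closed-form least-squares solution (SVD with reflection
guard) returns the transform plus the fiducial registration error (FRE),
the RMS residual after alignment.  For an AR system driven by a tracked
marker seated on a surgical guide, the patient-to-image registration is a
pure composition::

    T_anatomy<-marker = T_anatomy<-guide  (guide seating)
                      @ T_guide<-marker   (holder design pose)

so accuracy is governed by the seating and the marker pose estimate, not
by intra-operative landmark digitization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import RigidTransform, compose

__all__ = ["FiducialSet", "DegenerateGeometryError", "horn_register",
           "target_errors", "marker_to_patient"]


class DegenerateGeometryError(ValueError):
    """Fiducial configuration does not determine a unique rigid transform."""


@dataclass
class FiducialSet:
    """Labeled 3D landmark list in one named frame (RAS, mm)."""

    points: np.ndarray
    labels: list[str] = field(default_factory=list)
    frame: str = "anatomy"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not self.labels:
            self.labels = [f"F-{i + 1}" for i in range(len(self.points))]
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points length mismatch")
        self.labels = [str(x) for x in self.labels]

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, t: RigidTransform) -> "FiducialSet":
        if t.child != self.frame:
            raise ValueError(f"transform maps from {t.child!r}, points are in {self.frame!r}")
        return FiducialSet(t.apply(self.points), list(self.labels), t.parent)

    def reordered_like(self, other: "FiducialSet") -> "FiducialSet":
        """Match this set's row order to ``other``'s labels."""
        idx = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in other.labels if l not in idx]
        if missing:
            raise ValueError(f"labels missing from set: {missing}")
        order = [idx[l] for l in other.labels]
        return FiducialSet(self.points[order], list(other.labels), self.frame)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def _check_nondegenerate(p: np.ndarray) -> None:
    if len(p) < 3:
        raise DegenerateGeometryError("at least 3 fiducials are required")
    c = p - p.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    # rank < 2 => collinear (or coincident) points: rotation about the
    # line is unconstrained
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("fiducials are collinear or coincident")


def horn_register(moving: FiducialSet, fixed: FiducialSet) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping ``moving`` onto ``fixed``.

    Pairing is strictly by label.  Returns ``(T_fixed<-moving, FRE)`` where
    FRE is the root-mean-square residual distance after alignment.
    """
    if len(moving) != len(fixed):
        raise ValueError("point counts differ")
    mv = moving.reordered_like(fixed)
    P = mv.points
    Q = fixed.points
    _check_nondegenerate(P)
    _check_nondegenerate(Q)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    T = RigidTransform(R, t, parent=fixed.frame, child=moving.frame)
    resid = T.apply(P) - Q
    fre = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return T, fre


def target_errors(estimated: FiducialSet, truth: FiducialSet) -> np.ndarray:
    """Per-label Euclidean distance between corresponding points (mm)."""
    if sorted(estimated.labels) != sorted(truth.labels):
        raise ValueError("fiducial labels do not match")
    est = estimated.reordered_like(truth)
    return np.linalg.norm(est.points - truth.points, axis=1)


def marker_to_patient(holder_pose: RigidTransform, seating: RigidTransform) -> RigidTransform:
    """Compose the automatic registration chain ``T_anatomy<-marker``.

    ``holder_pose`` is the design-time marker pose in the guide frame
    (``T_guide<-marker``); ``seating`` is the guide's pose on the bone
    (``T_anatomy<-guide``).
    """
    return compose(seating, holder_pose)
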