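"""Rigid-transform algebra with named coordinate frames.

Every spatial relation in the toolkit (anatomy, guide, marker, camera,
world) is a proper rigid transform: a rotation ``R`` with ``det(R) = +1``
plus a translation in millimetres.  A transform carries the names of its
*parent* and *child* frames and maps child-frame coordinates into the
parent frame::

    p_parent = R @ p_child + t

Composition checks that the frame chain is consistent, which catches the
most common navigation-pipeline bug (applying a transform in the wrong
direction) at the point of use rather than as a silent accuracy loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "FrameChainError",
    "compose",
    "random_rigid",
    "rotation_from_axis_angle",
]

#: tolerance on ``R^T R - I`` for accepting a rotation matrix
_ORTHO_TOL = 1e-9


class FrameChainError(ValueError):
    """Raised when two transforms with incompatible frames are composed."""


def rotation_from_axis_angle(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about ``axis`` (need not be unit) by ``angle_rad``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    ux, uy, uz = axis / n
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer([ux, uy, uz], [ux, uy, uz])


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform mapping child-frame points into the parent frame.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Orthonormal with determinant +1 (checked on construction).
    translation : (3,) ndarray
        Offset in millimetres.
    parent, child : str
        Frame names; ``"anatomy" <- "guide"`` reads as ``T_anatomy<-guide``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    parent: str = "parent"
    child: str = "child"
    _skip_check: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not self._skip_check:
            err = np.abs(R.T @ R - np.eye(3)).max()
            if err > 1e-6:
                raise ValueError(f"rotation is not orthonormal (|R^T R - I| = {err:.3g})")
            if np.linalg.det(R) < 0:
                raise ValueError("rotation has negative determinant (improper)")

    # -- constructors ---------------------------------------------------
    @classmethod
    def identity(cls, parent: str = "parent", child: str = "child") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), parent, child)

    @classmethod
    def from_matrix(cls, m: np.ndarray, parent: str = "parent", child: str = "child") -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major, points as columns)."""
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3], parent, child)

    # -- core algebra ---------------------------------------------------
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) child-frame points into the parent frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation, self.child, self.parent)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    # -- diagnostics ----------------------------------------------------
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "parent": self.parent,
            "child": self.child,
            "matrix": [[float(v) for v in row] for row in self.matrix()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls.from_matrix(np.array(d["matrix"]), d.get("parent", "parent"), d.get("child", "child"))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """``a ∘ b``: map b's child frame into a's parent frame.

    Requires ``a.child == b.parent``; the middle frame cancels.
    """
    if a.child != b.parent:
        raise FrameChainError(
            f"cannot compose {a.parent}<-{a.child} with {b.parent}<-{b.child}: "
            f"middle frames {a.child!r} and {b.parent!r} differ"
        )
    return RigidTransform(
        a.rotation @ b.rotation,
        a.rotation @ b.translation + a.translation,
        a.parent,
        b.child,
    )


def random_rigid(
    rng: np.random.Generator,
    max_translation_mm: float = 100.0,
    parent: str = "parent",
    child: str = "child",
) -> RigidTransform:
    """Uniformly random rotation (QR-based Haar sampling) + uniform translation."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    return RigidTransform(Q, t, parent, child)
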