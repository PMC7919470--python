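"""CT segmentation post-processing.

Mirrors the mask clean-up a clinical engineer performs before 3D printing:
intensity thresholding of the bone, removal of disconnected components
(scanner bed, cushions), morphological hole filling so the printed part is
solid, and iso-surface extraction to a millimetre-space triangle mesh.

Volumes use a fixed RAS (right-anterior-superior) axis convention with
0-based voxel indices; physical position of voxel ``(i, j, k)`` is
``origin + index * spacing``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .mesh import SurfaceMesh, mesh_from_field

__all__ = ["VolumeImage", "LabelMask", "threshold_mask", "keep_largest_components",
           "fill_holes", "extract_surface"]

log = logging.getLogger(__name__)


@dataclass
class VolumeImage:
    """Scalar 3D image with voxel spacing and origin in mm (RAS)."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("volume must be a non-empty 3D grid")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if (self.spacing <= 0).any():
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelMask(VolumeImage):
    """Binary mask sharing the geometry contract of :class:`VolumeImage`."""

    label: str = "label"

    def __post_init__(self) -> None:
        super().__post_init__()
        v = np.asarray(self.voxels)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask voxels must be 0 or 1")
        self.voxels = v.astype(np.uint8)

    def count(self) -> int:
        return int(self.voxels.sum())


def threshold_mask(volume: VolumeImage, low: float, high: float = np.inf,
                   label: str = "bone") -> LabelMask:
    """Binary mask of voxels with intensity in ``[low, high]``.

    This is the first bone-segmentation step; threshold values are
    scanner- and case-dependent and must be supplied by the user.
    """
    if low > high:
        raise ValueError(f"invalid intensity range: low={low} > high={high}")
    m = ((volume.voxels >= low) & (volume.voxels <= high)).astype(np.uint8)
    return LabelMask(m, volume.spacing.copy(), volume.origin.copy(), label=label)


# 26-neighbourhood: voxels sharing a face, edge or corner are connected
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def keep_largest_components(mask: LabelMask, n_keep: int = 1) -> LabelMask:
    """Keep only the ``n_keep`` largest 26-connected components.

    The digital analogue of the "islands" clean-up that removes the
    clinical bed and other disconnected structures from a bone mask.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if mask.count() == 0:
        log.warning("keep_largest_components: input mask is empty")
        return LabelMask(mask.voxels.copy(), mask.spacing.copy(), mask.origin.copy(), label=mask.label)
    labeled, n = ndimage.label(mask.voxels, structure=_STRUCT_26)
    if n <= n_keep:
        return LabelMask(mask.voxels.copy(), mask.spacing.copy(), mask.origin.copy(), label=mask.label)
    sizes = np.bincount(labeled.ravel())[1:]  # skip background
    keep = np.argsort(sizes)[::-1][:n_keep] + 1
    out = np.isin(labeled, keep).astype(np.uint8)
    return LabelMask(out, mask.spacing.copy(), mask.origin.copy(), label=mask.label)


def fill_holes(mask: LabelMask, kernel: tuple[int, int, int] = (7, 7, 3)) -> LabelMask:
    """Morphological closing with a rectangular structuring element.

    The default 7x7x3 voxel kernel (in-plane x in-plane x slice) closes
    small cavities and channels that would print poorly.  Closing is
    extensive (output contains the input) and idempotent.
    """
    kernel = tuple(int(k) for k in kernel)
    if len(kernel) != 3 or any(k < 1 or k % 2 == 0 for k in kernel):
        raise ValueError(f"kernel dimensions must be odd and >= 1, got {kernel}")
    struct = np.ones(kernel, dtype=bool)
    # pad so dilation near the array border is not clipped by the edge,
    # which would violate the superset property
    pad = [(k, k) for k in kernel]
    padded = np.pad(mask.voxels.astype(bool), pad, mode="constant")
    closed = ndimage.binary_closing(padded, structure=struct)
    sl = tuple(slice(k, -k) for k in kernel)
    out = closed[sl] | mask.voxels.astype(bool)
    return LabelMask(out.astype(np.uint8), mask.spacing.copy(), mask.origin.copy(), label=mask.label)


def extract_surface(mask: LabelMask, level: float = 0.5, smooth_sigma: float = 0.0) -> SurfaceMesh:
    """Iso-surface of a binary mask as a watertight mesh in mm coordinates.

    The mask is zero-padded so the surface closes at the grid boundary;
    vertices are mapped to physical space with the volume's spacing and
    origin.  ``smooth_sigma`` (voxels) optionally smooths the indicator
    before meshing; off by default.
    """
    if mask.count() == 0:
        raise ValueError("cannot extract a surface from an empty mask")
    vol = np.pad(mask.voxels.astype(np.float32), 1, mode="constant")
    if smooth_sigma > 0:
        vol = ndimage.gaussian_filter(vol, smooth_sigma)
    # meshing in index space then scaling anisotropically keeps the
    # 0.5-level geometry aligned with voxel centres
    field = level - vol  # negative inside, so orientation comes out outward
    m = mesh_from_field(field, origin=np.zeros(3), pitch=1.0, level=0.0, label=mask.label)
    verts = (m.vertices - 1.0) * mask.spacing + mask.origin
    return SurfaceMesh(verts, m.faces, label=mask.label)
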