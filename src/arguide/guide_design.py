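"""Patient-specific surgical-guide generation.

A surgical guide is the negative of a bone surface region: a contact
patch is selected around a seed point, offset outward by the guide
thickness, and closed into a watertight solid whose inner surface carries
the exact bone curvature — which is what makes the guide seat in one
unique position.  The solid is then edited with screw holes (default
Ø 5 mm), conical validation fiducials (Ø 4 mm x 3 mm deep), and a socket
that holds the cubic AR marker at a known design pose, the anchor of the
automatic patient-to-image registration chain.

Mesh booleans run through a sampled signed-distance field followed by
marching-cubes remeshing.  Sampling the true SDF (rather than a binary
occupancy) keeps the boolean result sub-voxel accurate away from sharp
creases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import MeshQuery, SurfaceMesh, geodesic_distances, mesh_from_field, sample_field
from .transforms import RigidTransform, rotation_from_axis_angle

__all__ = ["GuideModel", "CuttingPlane", "FitResult", "SeedOffSurfaceError",
           "select_contact_region", "build_guide", "add_screw_holes",
           "add_marker_holder", "add_cone_fiducials", "extract_bone_fragment",
           "fit_guide"]

log = logging.getLogger(__name__)


class SeedOffSurfaceError(ValueError):
    """Seed point is too far from the bone surface to select a patch."""


@dataclass
class CuttingPlane:
    """Bounded osteotomy plane: point + unit normal + rectangle extents (mm)."""

    point: np.ndarray
    normal: np.ndarray
    extents: tuple[float, float] = (50.0, 50.0)

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        ln = np.linalg.norm(n)
        if not np.isclose(ln, 1.0, atol=1e-6):
            raise ValueError("cutting-plane normal must be unit length")
        self.normal = n / ln


@dataclass
class GuideModel:
    """Surgical guide: solid body plus its design metadata.

    ``holder_pose`` is ``T_guide<-marker``: where the AR marker sits, by
    design, in the guide frame (the guide frame coincides with the
    anatomy frame at the designed seating).
    """

    body: SurfaceMesh
    contact_patch: SurfaceMesh
    screw_axes: list = field(default_factory=list)       # (entry (3,), direction (3,), diameter mm)
    fiducial_cones: list = field(default_factory=list)   # (point (3,), inward normal (3,), diameter, depth)
    holder_pose: RigidTransform | None = None
    thickness_mm: float = 3.0

    def fiducial_points(self) -> np.ndarray:
        return np.array([c[0] for c in self.fiducial_cones]).reshape(-1, 3)

    def to_dict(self) -> dict:
        """JSON-serializable design sidecar (matrices row-major, mm)."""
        d = {
            "thickness_mm": float(self.thickness_mm),
            "screw_axes": [
                {"entry": list(map(float, e)), "direction": list(map(float, v)), "diameter_mm": float(dia)}
                for e, v, dia in self.screw_axes
            ],
            "fiducial_cones": [
                {"point": list(map(float, p)), "normal": list(map(float, n)),
                 "diameter_mm": float(dia), "depth_mm": float(dep)}
                for p, n, dia, dep in self.fiducial_cones
            ],
        }
        if self.holder_pose is not None:
            d["holder_pose"] = self.holder_pose.to_dict()
        return d


# ----------------------------------------------------------------------
# contact patch
# ----------------------------------------------------------------------

def select_contact_region(bone: SurfaceMesh, seed: np.ndarray, radius: float,
                          max_seed_distance: float = 2.0) -> SurfaceMesh:
    """Connected sub-mesh within geodesic ``radius`` of the seed point.

    The seed is snapped to the nearest bone-surface point (it must lie
    within ``max_seed_distance`` of the surface); distances are geodesic
    along the surface so the patch never jumps across thin gaps the way a
    Euclidean ball would.
    """
    if radius <= 0:
        raise ValueError("patch radius must be positive")
    seed = np.asarray(seed, dtype=float).reshape(3)
    q = MeshQuery(bone)
    d, cp, fidx, _ = q.closest(seed[None])
    if d[0] > max_seed_distance:
        raise SeedOffSurfaceError(
            f"seed is {d[0]:.2f} mm from the bone surface (limit {max_seed_distance} mm)")
    # anchor at the nearest vertex of the nearest face
    face = bone.faces[fidx[0]]
    anchor = int(face[np.argmin(np.linalg.norm(bone.vertices[face] - cp[0], axis=1))])
    g = geodesic_distances(bone, anchor)
    fmask = g[bone.faces].mean(axis=1) <= radius
    if not fmask.any():
        fmask = np.zeros(bone.n_faces, dtype=bool)
        fmask[fidx[0]] = True
    patch = bone.submesh(fmask, label="contact_patch")
    # keep only the component containing the seed
    comps = patch.face_connected_components()
    pq = MeshQuery(patch)
    _, _, pf, _ = pq.closest(cp)
    patch = patch.submesh(comps == comps[pf[0]], label="contact_patch")
    return patch


# ----------------------------------------------------------------------
# guide body
# ----------------------------------------------------------------------

def build_guide(patch: SurfaceMesh, thickness: float = 3.0) -> GuideModel:
    """Offset the contact patch outward and close it into a watertight solid.

    The inner surface *is* the patch (exact bone negative); the outer
    surface is the patch offset by ``thickness`` along vertex normals; the
    rim is stitched between the boundary loops.  If the offset
    self-intersects into an invalid solid, a voxel-remesh fallback
    rebuilds the body approximately (with a warning).
    """
    if thickness <= 0:
        raise ValueError("guide thickness must be positive")
    if patch.n_faces == 0:
        raise ValueError("contact patch is empty")
    if patch.is_watertight():
        raise ValueError("contact patch must be an open surface, not a closed solid")
    vn = patch.vertex_normals()
    outer_v = patch.vertices + thickness * vn
    n = patch.n_vertices
    verts = np.vstack([patch.vertices, outer_v])
    inner_faces = patch.faces[:, ::-1]           # faces toward the bone
    outer_faces = patch.faces + n
    wall_faces = []
    for loop in _face_direction_loops(patch):
        for a, b in zip(loop, np.roll(loop, -1)):
            wall_faces.append([a, b, b + n])
            wall_faces.append([a, b + n, a + n])
    body = SurfaceMesh(verts, np.vstack([inner_faces, outer_faces, np.array(wall_faces)]),
                       label="guide")
    if body.signed_volume() < 0:
        body = body.flipped()
    if not body.is_watertight():
        log.warning("offset guide body is not watertight; falling back to voxel remesh")
        body = _voxel_offset_body(patch, thickness)
    return GuideModel(body=body, contact_patch=patch, thickness_mm=float(thickness))


def _face_direction_loops(patch: SurfaceMesh) -> list[np.ndarray]:
    """Boundary loops ordered along the face winding direction."""
    be = patch.boundary_edges()
    bset = {tuple(x) for x in be}
    nxt: dict[int, int] = {}
    face_edges = np.concatenate(
        [patch.faces[:, [0, 1]], patch.faces[:, [1, 2]], patch.faces[:, [2, 0]]])
    for a, b in face_edges:
        key = (a, b) if a < b else (b, a)
        if key in bset:
            nxt[int(a)] = int(b)
    loops = []
    remaining = dict(nxt)
    while remaining:
        start = next(iter(remaining))
        loop = [start]
        cur = remaining.pop(start)
        while cur != start and cur in remaining:
            loop.append(cur)
            cur = remaining.pop(cur)
        loops.append(np.array(loop, dtype=np.int64))
    return loops


def _voxel_offset_body(patch: SurfaceMesh, thickness: float, pitch: float = 0.5) -> SurfaceMesh:
    """Approximate offset solid via an SDF built from patch closest points."""
    q = MeshQuery(patch)
    vn = patch.vertex_normals()

    def sdf(pts: np.ndarray) -> np.ndarray:
        d, cp, f, bary = q.closest(pts)
        nrm = np.einsum("qk,qkj->qj", bary, vn[patch.faces[f]])
        nrm /= np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-12)
        s = np.einsum("ij,ij->i", pts - cp, nrm)
        lateral = np.sqrt(np.maximum(d * d - s * s, 0.0))
        return np.maximum.reduce([-s, s - thickness, lateral - pitch])

    lo = patch.bounds()[0] - thickness
    hi = patch.bounds()[1] + thickness
    f, o = sample_field(sdf, np.array([lo, hi]), pitch)
    return mesh_from_field(f, o, pitch, label="guide")


# ----------------------------------------------------------------------
# SDF boolean editing
# ----------------------------------------------------------------------

def _auto_pitch(mesh: SurfaceMesh, feature_mm: float) -> float:
    """Grid pitch resolving ``feature_mm`` without an oversized grid."""
    ext = float(mesh.extents().max())
    return float(max(min(feature_mm / 8.0, ext / 64.0), ext / 400.0))


def _remesh_subtract(mesh: SurfaceMesh, cut_sdf, pitch: float, pad: float = 2.0) -> SurfaceMesh:
    """Remesh ``mesh`` minus the region where ``cut_sdf < 0``."""
    q = MeshQuery(mesh)

    def sdf(pts: np.ndarray) -> np.ndarray:
        return np.maximum(q.signed_distance(pts), -cut_sdf(pts))

    f, o = sample_field(sdf, mesh.bounds(), pitch, pad=pad)
    if (f < 0).sum() == 0:
        raise ValueError("boolean subtraction removed the whole solid")
    out = mesh_from_field(f, o, pitch, label=mesh.label)
    if not out.is_watertight():
        log.warning("remeshed boolean result is not watertight")
    return out


def _cylinder_line_sdf(entry: np.ndarray, direction: np.ndarray, radius: float):
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    e = np.asarray(entry, dtype=float)

    def sdf(pts: np.ndarray) -> np.ndarray:
        v = pts - e
        ax = v @ d
        rad = np.linalg.norm(v - ax[:, None] * d, axis=1)
        return rad - radius

    return sdf


def add_screw_holes(guide: GuideModel, axes: list, diameter: float = 5.0,
                    pitch: float | None = None) -> GuideModel:
    """Drill through-holes along the given axes (default Ø 5 mm).

    ``axes`` is a list of ``(entry_point, direction)`` pairs; each hole is
    an infinite cylinder about that line, so it pierces the body wherever
    the line does.  The body is remeshed; an axis that misses the body
    leaves the volume unchanged.
    """
    if diameter <= 0:
        raise ValueError("screw diameter must be positive")
    if not axes:
        return guide
    if pitch is None:
        pitch = _auto_pitch(guide.body, diameter)
    sdfs = [_cylinder_line_sdf(e, v, diameter / 2.0) for e, v in axes]

    def cut(pts: np.ndarray) -> np.ndarray:
        return np.minimum.reduce([s(pts) for s in sdfs])

    body = _remesh_subtract(guide.body, cut, pitch)
    new_axes = guide.screw_axes + [
        (np.asarray(e, dtype=float), np.asarray(v, dtype=float) / np.linalg.norm(v), float(diameter))
        for e, v in axes
    ]
    return replace(guide, body=body, screw_axes=new_axes)


def _cone_sdf(point: np.ndarray, inward_normal: np.ndarray, diameter: float, depth: float,
              overshoot: float = 2.0):
    """Conical pocket: rim Ø ``diameter`` at ``point``, apex ``depth`` along
    the inward normal, extended ``overshoot`` mm outward as a cylinder so
    the cut clears the surface."""
    n = np.asarray(inward_normal, dtype=float)
    n = n / np.linalg.norm(n)
    apex = np.asarray(point, dtype=float) + depth * n
    r = diameter / 2.0

    def sdf(pts: np.ndarray) -> np.ndarray:
        v = pts - apex
        h = -(v @ n)  # height above the apex, toward the surface
        rad = np.linalg.norm(v - (v @ n)[:, None] * n, axis=1)
        profile = np.clip(h, 0.0, depth) * (r / depth)
        slope_correction = np.cos(np.arctan2(r, depth))
        d_side = (rad - profile) * slope_correction
        return np.maximum.reduce([d_side, -h, h - (depth + overshoot)])

    return sdf


def add_cone_fiducials(mesh: SurfaceMesh, points: np.ndarray, diameter: float = 4.0,
                       depth: float = 3.0, pitch: float | None = None,
                       max_offset: float = 0.5) -> SurfaceMesh:
    """Subtract conical registration/measurement pockets at surface points.

    Each pocket has its rim circle (Ø ``diameter``) in the surface at the
    given point and its apex ``depth`` mm along the inward surface normal
    — the divot a tracked pointer tip can sit in reproducibly.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return mesh
    q = MeshQuery(mesh)
    d, cp, f, _ = q.closest(points)
    off = np.where(d > max_offset)[0]
    if len(off):
        raise ValueError(f"fiducial points off the surface (> {max_offset} mm): indices {off.tolist()}")
    normals = mesh.face_normals()[f]  # outward
    if pitch is None:
        pitch = min(depth, diameter) / 20.0
    sdfs = [_cone_sdf(cp[i], -normals[i], diameter, depth) for i in range(len(points))]

    def cut(pts: np.ndarray) -> np.ndarray:
        return np.minimum.reduce([s(pts) for s in sdfs])

    return _remesh_subtract(mesh, cut, pitch)


# ----------------------------------------------------------------------
# marker holder
# ----------------------------------------------------------------------

def add_marker_holder(guide: GuideModel, pose: RigidTransform,
                      marker_edge: float = 30.0, clearance: float = 0.2,
                      wall: float = 2.5, floor: float = 2.5,
                      insert_depth: float = 8.0, pitch: float = 0.5) -> GuideModel:
    """Attach the AR-marker socket and record the design pose exactly.

    ``pose`` is ``T_guide<-marker`` (marker frame: origin at cube centre,
    -z face against the adaptor).  The socket is an open-top pocket sized
    ``marker_edge + 2 * clearance`` so the cube slides in without contact;
    the stored ``holder_pose`` is the bit-exact design transform that the
    registration chain later inverts.
    """
    L = marker_edge
    cav = L + 2.0 * clearance
    R, t = pose.rotation, pose.translation
    # cube -z face centre in guide frame
    zq = R @ np.array([0.0, 0.0, 1.0])
    base_centre = t - (L / 2.0) * zq

    outer = np.array([cav + 2 * wall, cav + 2 * wall, insert_depth + floor])
    # socket local frame == marker orientation; socket top edge is at the
    # cube base + insert_depth
    centre_local_z = insert_depth / 2.0 + floor / 2.0 - floor  # z of box centre rel. cube base

    def box_sdf(half, centre):
        def f(pts_local):
            qd = np.abs(pts_local - centre) - half
            outside = np.linalg.norm(np.maximum(qd, 0.0), axis=1)
            inside = np.minimum(np.max(qd, axis=1), 0.0)
            return outside + inside
        return f

    outer_sdf = box_sdf(outer / 2.0, np.array([0.0, 0.0, centre_local_z]))
    # cavity: open at the top (extends beyond the outer box upward)
    cavity_sdf = box_sdf(np.array([cav / 2.0, cav / 2.0, insert_depth]),
                         np.array([0.0, 0.0, insert_depth]))

    def socket_sdf(pts: np.ndarray) -> np.ndarray:
        local = (pts - base_centre) @ R  # guide -> marker axes
        return np.maximum(outer_sdf(local), -cavity_sdf(local))

    lo = base_centre - outer.max()
    hi = base_centre + outer.max()
    fgrid, o = sample_field(socket_sdf, np.array([lo, hi]), pitch)
    socket = mesh_from_field(fgrid, o, pitch, label="marker_socket")

    # placement check: the socket must not invade the contact patch
    pq = MeshQuery(socket)
    if guide.contact_patch.n_vertices and (pq.signed_distance(guide.contact_patch.vertices) < 0).any():
        raise ValueError("marker-holder socket collides with the guide contact patch")

    body = guide.body.concatenated(socket, label="guide")
    return replace(guide, body=body, holder_pose=pose)


# ----------------------------------------------------------------------
# bone fragment
# ----------------------------------------------------------------------

def extract_bone_fragment(bone: SurfaceMesh, patch: SurfaceMesh, margin: float = 10.0,
                          pitch: float | None = None) -> SurfaceMesh:
    """Watertight sub-solid of the bone within ``margin`` mm of the patch.

    The printable rehearsal piece: big enough to seat the guide, far
    smaller than the whole segmented bone.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if pitch is None:
        pitch = _auto_pitch(bone, max(margin, 2.0))
    bq = MeshQuery(bone)
    pq = MeshQuery(patch)

    def sdf(pts: np.ndarray) -> np.ndarray:
        d_patch, _, _, _ = pq.closest(pts)
        return np.maximum(bq.signed_distance(pts), d_patch - margin)

    lo = np.maximum(patch.bounds()[0] - margin, bone.bounds()[0]) - 2 * pitch
    hi = np.minimum(patch.bounds()[1] + margin, bone.bounds()[1]) + 2 * pitch
    fgrid, o = sample_field(sdf, np.array([lo, hi]), pitch)
    if (fgrid < 0).sum() == 0:
        raise ValueError("patch neighbourhood does not intersect the bone solid")
    return mesh_from_field(fgrid, o, pitch, label="bone_fragment")


# ----------------------------------------------------------------------
# guide seating (trimmed point-to-plane ICP)
# ----------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of :func:`fit_guide`."""

    pose: RigidTransform      # refined T_anatomy<-guide
    rms_mm: float             # trimmed RMS contact distance at the refined pose
    converged: bool
    n_iter: int

    def __iter__(self):
        yield self.pose
        yield self.rms_mm


def fit_guide(guide: GuideModel, bone: SurfaceMesh, init: RigidTransform | None = None,
              max_iter: int = 60, trim_fraction: float = 0.10,
              tol_mm: float = 1e-4, query: MeshQuery | None = None) -> FitResult:
    """Refine the guide seating by trimmed point-to-plane ICP.

    The contact-patch vertices (guide frame) are matched to their closest
    bone-surface points; the worst ``trim_fraction`` of pairs is dropped
    each iteration (tolerates partial overlap); convergence when the
    trimmed RMS changes by less than ``tol_mm``.
    """
    if init is None:
        init = RigidTransform.identity(parent="anatomy", child="guide")
    src = guide.contact_patch.vertices
    if len(src) < 6:
        raise ValueError("contact patch has too few vertices for ICP")
    q = query if query is not None else MeshQuery(bone)
    fn = bone.face_normals()
    pose = init
    keep = max(6, int(np.ceil(len(src) * (1.0 - trim_fraction))))
    prev_rms = np.inf
    rms = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = pose.apply(src)
        d, cp, f, _ = q.closest(p)
        order = np.argsort(d)[:keep]
        rms = float(np.sqrt((d[order] ** 2).mean()))
        if abs(prev_rms - rms) < tol_mm:
            converged = True
            break
        prev_rms = rms
        pk, qk, nk = p[order], cp[order], fn[f[order]]
        A = np.hstack([np.cross(pk, nk), nk])
        b = -np.einsum("ij,ij->i", pk - qk, nk)
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        w, dt = x[:3], x[3:]
        ang = np.linalg.norm(w)
        dR = rotation_from_axis_angle(w, ang) if ang > 1e-15 else np.eye(3)
        delta = RigidTransform(dR, dt, parent=pose.parent, child=pose.parent, _skip_check=False)
        pose = RigidTransform(delta.rotation @ pose.rotation,
                              delta.rotation @ pose.translation + delta.translation,
                              pose.parent, pose.child)
    # final residual at the returned pose
    d, _, _, _ = q.closest(pose.apply(src))
    order = np.argsort(d)[:keep]
    rms = float(np.sqrt((d[order] ** 2).mean()))
    return FitResult(pose=pose, rms_mm=rms, converged=converged, n_iter=it)
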