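"""Synthetic validation phantoms and the virtual accuracy experiments.

Each phantom emulates a 3D-printed patient-specific test object: a
representative bone region (with an adjacent tumor), support struts and a
stand base for rigidity, eight conical surface fiducials (Ø 4 mm x 3 mm)
for point-based registration, and a seated surgical guide carrying 3-5 of
its own conical fiducials plus the holder pose of a 30 mm cubic AR
marker.  Geometry is built from analytic signed-distance primitives and
meshed once with marching cubes, so a given seed reproduces the phantom
bit-for-bit.

Two virtual experiments mirror the physical validation protocol:

* ``placement_trial`` — seat the guide with a perturbed pose, let ICP
  re-seat it, digitize the guide fiducials with localization noise,
  register phantom-to-model through the eight surface fiducials, and
  report per-fiducial Euclidean error (*guide placement error*).
* ``tracking_trial`` — push surface targets through the registration
  chain anatomy <- seating <- holder <- *observed* marker pose, add
  pointer noise, and report per-target Euclidean error (*AR tracking
  error*), together with each target's distance to the marker (the
  lever arm).

``run_experiment`` runs the full factorial cases x users x repetitions
design (two users, five repetitions by default).  Users are independent
RNG streams with identical noise parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .guide_design import GuideModel, build_guide, fit_guide, select_contact_region
from .marker import MarkerModel, simulate_marker_observation
from .mesh import MeshQuery, SurfaceMesh, farthest_point_indices, mesh_from_field, sample_field
from .registration import FiducialSet, horn_register, target_errors
from .transforms import RigidTransform, random_rigid, rotation_from_axis_angle

__all__ = ["PhantomSpec", "Phantom", "TrialResult", "PlacementNoise", "TrackingNoise",
           "generate_phantom", "placement_trial", "tracking_trial", "run_experiment",
           "default_phantom_specs", "trials_to_dataframe"]

FIDUCIAL_DIAMETER_MM = 4.0
FIDUCIAL_DEPTH_MM = 3.0


# ----------------------------------------------------------------------
# specs and noise models
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic phantom."""

    case_id: str
    dims_mm: tuple[float, float, float]
    bone_kind: str = "tube"            # tube | ellipsoid | composite
    n_surface_fiducials: int = 8
    n_guide_fiducials: int = 4
    seed: int = 0
    pitch_mm: float | None = None      # marching-cubes grid pitch; None -> dims-scaled
    patch_radius_mm: float | None = None
    guide_thickness_mm: float = 3.0

    def __post_init__(self) -> None:
        d = np.asarray(self.dims_mm, dtype=float)
        if (d <= 0).any() or len(d) != 3:
            raise ValueError("phantom dimensions must be three positive lengths (mm)")
        if not 3 <= self.n_guide_fiducials <= 5:
            raise ValueError("guides carry 3 to 5 conical fiducials")
        if self.n_surface_fiducials < 3:
            raise ValueError("at least 3 surface fiducials are required for registration")
        if self.bone_kind not in ("tube", "ellipsoid", "composite"):
            raise ValueError(f"unknown bone kind {self.bone_kind!r}")


def default_phantom_specs() -> list[PhantomSpec]:
    """The six stock phantoms (overall sizes follow the validated cases)."""
    table = [  # case id, dims (mm), bone kind, guide fiducial count
        ("AR3DP0002", (170.0, 150.0, 130.0), "ellipsoid", 4),
        ("AR3DP0003", (120.0, 110.0, 90.0), "tube", 3),
        ("AR3DP0004", (220.0, 220.0, 190.0), "composite", 5),
        ("AR3DP0005", (160.0, 100.0, 50.0), "tube", 3),
        ("AR3DP0006", (170.0, 150.0, 100.0), "composite", 4),
        ("AR3DP0007", (220.0, 120.0, 110.0), "tube", 5),
    ]
    return [PhantomSpec(cid, dims, kind, n_guide_fiducials=ngf, seed=i + 1)
            for i, (cid, dims, kind, ngf) in enumerate(table)]


@dataclass(frozen=True)
class PlacementNoise:
    """Noise model for the guide-placement experiment (all sigmas >= 0)."""

    seating_trans_mm: float = 0.5
    seating_rot_deg: float = 0.5
    fiducial_sigma_mm: float = 0.5   # per-axis localization noise (FLE)

    def __post_init__(self):
        if min(self.seating_trans_mm, self.seating_rot_deg, self.fiducial_sigma_mm) < 0:
            raise ValueError("noise sigmas must be non-negative")

    @classmethod
    def zero(cls) -> "PlacementNoise":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class TrackingNoise:
    """Noise model for the AR tracking experiment (all sigmas >= 0)."""

    marker_trans_mm: float = 0.5
    marker_rot_deg: float = 0.5
    seating_trans_mm: float = 0.5
    seating_rot_deg: float = 0.5
    pointer_sigma_mm: float = 0.5

    def __post_init__(self):
        vals = (self.marker_trans_mm, self.marker_rot_deg, self.seating_trans_mm,
                self.seating_rot_deg, self.pointer_sigma_mm)
        if min(vals) < 0:
            raise ValueError("noise sigmas must be non-negative")

    @classmethod
    def zero(cls) -> "TrackingNoise":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


# ----------------------------------------------------------------------
# phantom
# ----------------------------------------------------------------------

@dataclass
class Phantom:
    """One synthetic phantom with its designed guide and ground truth."""

    spec: PhantomSpec
    bone: SurfaceMesh
    tumor: SurfaceMesh
    support: SurfaceMesh            # struts + stand base
    body: SurfaceMesh               # union bone+struts+base (target sampling surface)
    fiducials: FiducialSet          # 8 surface fiducial points, anatomy frame
    fiducial_normals: np.ndarray    # outward normals at the fiducials
    guide: GuideModel
    seating_truth: RigidTransform   # T_anatomy<-guide at the designed seating
    marker: MarkerModel
    _bone_query: MeshQuery | None = field(default=None, repr=False, compare=False)

    @property
    def case_id(self) -> str:
        return self.spec.case_id

    def bone_query(self) -> MeshQuery:
        if self._bone_query is None:
            self._bone_query = MeshQuery(self.bone)
        return self._bone_query

    def marker_center_anatomy(self) -> np.ndarray:
        """Marker-cube centre in the anatomy frame at the designed seating."""
        return self.seating_truth.apply(self.guide.holder_pose.translation)


def _box_sdf(half: np.ndarray, centre: np.ndarray):
    def f(p):
        q = np.abs(p - centre) - half
        return (np.linalg.norm(np.maximum(q, 0.0), axis=1)
                + np.minimum(np.max(q, axis=1), 0.0))
    return f


def _capsule_sdf(a: np.ndarray, b: np.ndarray, radius: float):
    ab = b - a
    den = float(ab @ ab)

    def f(p):
        t = np.clip(((p - a) @ ab) / den, 0.0, 1.0)
        return np.linalg.norm(p - (a + t[:, None] * ab), axis=1) - radius
    return f


def _ellipsoid_sdf(centre: np.ndarray, semi: np.ndarray):
    def f(p):
        q = (p - centre) / semi
        k = np.linalg.norm(q, axis=1)
        return (k - 1.0) * semi.min()  # scaled bound, exact sign
    return f


def _bumps(rng: np.random.Generator, n: int, centres_box: np.ndarray, amp: float, width: float):
    """Smooth random Gaussian surface bumps; break symmetry of the primitives."""
    c = rng.uniform(centres_box[0], centres_box[1], size=(n, 3))
    a = rng.uniform(0.4, 1.0, n) * amp * rng.choice([-1.0, 1.0], n)
    w2 = (rng.uniform(0.7, 1.3, n) * width) ** 2

    def f(p):
        out = np.zeros(len(p))
        for i in range(n):
            out += a[i] * np.exp(-((p - c[i]) ** 2).sum(axis=1) / w2[i])
        return out
    return f


def _bone_sdf(spec: PhantomSpec, rng: np.random.Generator):
    """Asymmetric bone-like solid fitted inside the phantom dimensions."""
    d = np.asarray(spec.dims_mm, dtype=float)
    margin = 0.06 * d + 2.0
    half = d / 2.0 - margin
    zc = 0.25 * half[2]  # bone sits above centre, base below
    r0 = float(min(half[1], half[2]) * 0.35)
    bump = _bumps(rng, 6, np.array([[-half[0], -half[1], zc - r0], [half[0], half[1], zc + r0]]),
                  amp=0.35 * r0, width=1.2 * r0)
    if spec.bone_kind == "ellipsoid":
        core = _ellipsoid_sdf(np.array([0.0, 0.0, zc]), np.array([half[0] * 0.85, r0 * 1.4, r0 * 1.2]))
    elif spec.bone_kind == "composite":
        shaft = _capsule_sdf(np.array([-half[0] * 0.85, 0.0, zc]), np.array([half[0] * 0.85, 0.0, zc]), r0)
        branch = _capsule_sdf(np.array([0.0, 0.0, zc]), np.array([half[0] * 0.3, half[1] * 0.6, zc + r0 * 0.5]),
                              0.8 * r0)
        core = lambda p: np.minimum(shaft(p), branch(p))
    else:  # tube
        core = _capsule_sdf(np.array([-half[0] * 0.85, 0.0, zc]), np.array([half[0] * 0.85, 0.0, zc]), r0)

    def f(p):
        return core(p) + bump(p)
    return f, zc, r0, half


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically build a phantom from its spec (same seed, same bits)."""
    rng = np.random.default_rng(spec.seed)
    d = np.asarray(spec.dims_mm, dtype=float)
    bone_sdf, zc, r0, half = _bone_sdf(spec, rng)
    pitch = spec.pitch_mm if spec.pitch_mm is not None else float(max(d.max() / 80.0, 1.0))

    # stand base and two support struts
    base_half = np.array([half[0] * 0.8, half[1] * 0.8, 3.0])
    base_z = -d[2] / 2.0 + base_half[2] + 0.5
    base = _box_sdf(base_half, np.array([0.0, 0.0, base_z]))
    caps = [
        _capsule_sdf(np.array([sx * half[0] * 0.5, 0.0, base_z]),
                     np.array([sx * half[0] * 0.5, 0.0, zc]), 0.35 * r0)
        for sx in (-1.0, 1.0)
    ]
    # clip the strut end-spheres at the base mid-plane so they stay
    # buried inside the slab (keeps the union inside the stated bbox)
    struts = [lambda p, c=c: np.maximum(c(p), base_z - p[:, 2]) for c in caps]
    support_sdf = lambda p: np.minimum(base(p), np.minimum(struts[0](p), struts[1](p)))
    body_sdf = lambda p: np.minimum(bone_sdf(p), support_sdf(p))

    bounds = np.array([-d / 2.0, d / 2.0])
    fb, ob = sample_field(bone_sdf, bounds, pitch, pad=1.0)
    bone = mesh_from_field(fb, ob, pitch, label="bone")
    fs, os_ = sample_field(support_sdf, bounds, pitch, pad=1.0)
    support = mesh_from_field(fs, os_, pitch, label="support")
    fy, oy = sample_field(body_sdf, bounds, pitch, pad=1.0)
    body = mesh_from_field(fy, oy, pitch, label="phantom_body")

    # tumor: ellipsoid pressed against the bone flank
    tum_c = np.array([0.15 * half[0], -r0 * 0.9, zc + 0.3 * r0])
    tum_semi = np.array([0.35 * half[0], 0.9 * r0, 0.9 * r0])
    ft, ot = sample_field(_ellipsoid_sdf(tum_c, tum_semi), bounds, pitch, pad=1.0)
    tumor = mesh_from_field(ft, ot, pitch, label="tumor")

    # eight conical surface fiducials, spread over the upper bone surface
    vn = bone.vertex_normals()
    upper = np.where(bone.vertices[:, 2] > zc - 0.2 * r0)[0]
    pick = upper[farthest_point_indices(bone.vertices[upper], spec.n_surface_fiducials, rng)]
    fiducials = FiducialSet(bone.vertices[pick].copy(),
                            [f"F-{i + 1}" for i in range(len(pick))], frame="anatomy")
    fid_normals = vn[pick].copy()

    # surgical guide on the upper mid-shaft
    top_candidates = upper[bone.vertices[upper, 2] > np.percentile(bone.vertices[upper, 2], 75)]
    seed_vertex = top_candidates[np.argmin(np.abs(bone.vertices[top_candidates, 0] - 0.2 * half[0]))]
    patch_radius = spec.patch_radius_mm if spec.patch_radius_mm is not None else \
        float(np.clip(0.35 * half[0], 12.0, 25.0))
    patch = select_contact_region(bone, bone.vertices[seed_vertex], patch_radius)
    guide = build_guide(patch, spec.guide_thickness_mm)

    # guide fiducials on the outer guide surface
    outer_pts = patch.vertices + spec.guide_thickness_mm * patch.vertex_normals()
    gpick = farthest_point_indices(outer_pts, spec.n_guide_fiducials, rng)
    gnorm = patch.vertex_normals()[gpick]
    guide = replace(guide, fiducial_cones=[
        (outer_pts[i].copy(), -gnorm[j].copy(), FIDUCIAL_DIAMETER_MM, FIDUCIAL_DEPTH_MM)
        for j, i in enumerate(gpick)
    ])

    # marker holder pose: cube centre above the patch centre, +z outward
    centre = patch.centroid()
    _, cp, f, _ = MeshQuery(patch).closest(centre[None])
    nz = patch.face_normals()[f[0]]
    ref = np.array([1.0, 0.0, 0.0]) if abs(nz[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    nx = np.cross(ref, nz)
    nx /= np.linalg.norm(nx)
    ny = np.cross(nz, nx)
    stand_off = spec.guide_thickness_mm + 2.5 + MarkerModel().edge_mm / 2.0 + 2.0
    holder_pose = RigidTransform(np.column_stack([nx, ny, nz]), cp[0] + stand_off * nz,
                                 parent="guide", child="marker")
    guide = replace(guide, holder_pose=holder_pose)

    return Phantom(
        spec=spec, bone=bone, tumor=tumor, support=support, body=body,
        fiducials=fiducials, fiducial_normals=fid_normals, guide=guide,
        seating_truth=RigidTransform.identity(parent="anatomy", child="guide"),
        marker=MarkerModel(),
    )


# ----------------------------------------------------------------------
# trials
# ----------------------------------------------------------------------

@dataclass
class TrialResult:
    """Per-trial navigation errors with their experimental labels."""

    case_id: str
    user: int
    rep: int
    kind: str                        # "placement" | "tracking"
    errors_mm: np.ndarray
    target_points: np.ndarray        # anatomy frame
    distance_to_marker_mm: np.ndarray
    fre_mm: float = np.nan
    seating_rms_mm: float = np.nan
    fit_converged: bool = True

    def __post_init__(self):
        self.errors_mm = np.asarray(self.errors_mm, dtype=float).ravel()
        if (self.errors_mm < 0).any():
            raise ValueError("errors must be non-negative")


def _perturbed_seating(phantom: Phantom, s_trans: float, s_rot_deg: float,
                       rng: np.random.Generator) -> tuple[RigidTransform, float, bool]:
    """Imperfect manual placement followed by ICP re-seating."""
    truth = phantom.seating_truth
    if s_trans == 0 and s_rot_deg == 0:
        return truth, 0.0, True
    axis = rng.standard_normal(3)
    ang = abs(rng.normal(0.0, np.radians(s_rot_deg))) if s_rot_deg > 0 else 0.0
    dR = rotation_from_axis_angle(axis, ang) if ang > 0 else np.eye(3)
    dt = rng.normal(0.0, s_trans, 3) if s_trans > 0 else np.zeros(3)
    init = RigidTransform(truth.rotation @ dR, truth.translation + dt, truth.parent, truth.child)
    fit = fit_guide(phantom.guide, phantom.bone, init, query=phantom.bone_query())
    return fit.pose, fit.rms_mm, fit.converged


def placement_trial(phantom: Phantom, noise: PlacementNoise = PlacementNoise(),
                    user: int = 1, rep: int = 1, seed: int | np.random.Generator = 0) -> TrialResult:
    """One removal-and-reseating of the guide, digitized and registered.

    The phantom is placed at a random rigid pose in the tracker (world)
    frame; its eight surface fiducials are digitized with per-axis
    Gaussian noise and registered back to the design; the guide's conical
    fiducials, digitized with the same noise, are mapped through that
    registration and compared against their designed positions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    world = random_rigid(rng, 50.0, parent="world", child="anatomy")
    seating, seat_rms, ok = _perturbed_seating(phantom, noise.seating_trans_mm,
                                               noise.seating_rot_deg, rng)

    fid_world = world.apply(phantom.fiducials.points)
    if noise.fiducial_sigma_mm > 0:
        fid_world = fid_world + rng.normal(0.0, noise.fiducial_sigma_mm, fid_world.shape)
    measured = FiducialSet(fid_world, list(phantom.fiducials.labels), frame="world")
    reg, fre = horn_register(measured, phantom.fiducials)  # T_anatomy<-world

    g_design = phantom.guide.fiducial_points()             # guide frame == design
    g_world = world.apply(seating.apply(g_design))
    if noise.fiducial_sigma_mm > 0:
        g_world = g_world + rng.normal(0.0, noise.fiducial_sigma_mm, g_world.shape)
    labels = [f"G-{i + 1}" for i in range(len(g_design))]
    est = FiducialSet(reg.apply(g_world), labels, frame="anatomy")
    truth = FiducialSet(phantom.seating_truth.apply(g_design), labels, frame="anatomy")
    errs = target_errors(est, truth)

    mc = phantom.marker_center_anatomy()
    dist = np.linalg.norm(truth.points - mc, axis=1)
    return TrialResult(phantom.case_id, user, rep, "placement", errs, truth.points,
                       dist, fre_mm=fre, seating_rms_mm=seat_rms, fit_converged=ok)


def tracking_trial(phantom: Phantom, marker: MarkerModel | None = None,
                   noise: TrackingNoise = TrackingNoise(), n_targets: int = 14,
                   user: int = 1, rep: int = 1,
                   seed: int | np.random.Generator = 0) -> TrialResult:
    """One AR visualization-accuracy trial with ``n_targets`` surface spheres.

    Targets are sampled area-uniformly on the phantom surface; their
    augmented positions follow the chain anatomy <- seating <- holder <-
    observed marker pose, and the 'pointer touch' adds per-axis Gaussian
    localization noise.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    marker = marker or phantom.marker
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    world = random_rigid(rng, 50.0, parent="world", child="anatomy")
    seating, seat_rms, ok = _perturbed_seating(phantom, noise.seating_trans_mm,
                                               noise.seating_rot_deg, rng)
    holder = phantom.guide.holder_pose
    true_marker_world = world @ seating @ holder  # T_world<-marker
    obs = simulate_marker_observation(true_marker_world,
                                      (noise.marker_trans_mm, noise.marker_rot_deg), rng)

    targets_anat, _ = phantom.body.sample_surface(n_targets, rng)
    # design-time chain assumes the nominal seating (identity): the app
    # stores models relative to the marker via the holder pose alone
    design_chain = phantom.seating_truth @ holder           # T_anatomy<-marker (design)
    targets_marker = design_chain.inverse().apply(targets_anat)
    augmented_world = obs.pose.apply(targets_marker)
    recorded = augmented_world
    if noise.pointer_sigma_mm > 0:
        recorded = recorded + rng.normal(0.0, noise.pointer_sigma_mm, recorded.shape)
    true_world = world.apply(targets_anat)
    errs = np.linalg.norm(recorded - true_world, axis=1)

    mc = phantom.marker_center_anatomy()
    dist = np.linalg.norm(targets_anat - mc, axis=1)
    return TrialResult(phantom.case_id, user, rep, "tracking", errs, targets_anat,
                       dist, seating_rms_mm=seat_rms, fit_converged=ok)


def run_experiment(phantoms: list[Phantom], users: int = 2, reps: int = 5,
                   noise: PlacementNoise | TrackingNoise | None = None,
                   n_targets: int = 14, kind: str = "tracking",
                   seed: int = 0) -> list[TrialResult]:
    """Full factorial cases x users x repetitions trial set, reproducible.

    Each (case, user, rep) gets an independent child RNG stream derived
    from the master seed, so per-user subsets are exchangeable and the
    whole table is reproducible from ``seed`` alone.
    """
    if users < 1 or reps < 1:
        raise ValueError("protocol counts must be >= 1")
    if kind not in ("placement", "tracking"):
        raise ValueError("kind must be 'placement' or 'tracking'")
    if noise is None:
        noise = TrackingNoise() if kind == "tracking" else PlacementNoise()
    out: list[TrialResult] = []
    for ci, ph in enumerate(phantoms):
        for user in range(1, users + 1):
            for rep in range(1, reps + 1):
                rng = np.random.default_rng([seed, ci, user, rep, 0 if kind == "placement" else 1])
                if kind == "placement":
                    out.append(placement_trial(ph, noise, user, rep, rng))
                else:
                    out.append(tracking_trial(ph, None, noise, n_targets, user, rep, rng))
    return out


def trials_to_dataframe(trials: list[TrialResult]) -> pd.DataFrame:
    """Long-format table: one row per target measurement."""
    rows = []
    for t in trials:
        for j, e in enumerate(t.errors_mm):
            rows.append({
                "case": t.case_id, "user": t.user, "rep": t.rep, "kind": t.kind,
                "target": j + 1, "error_mm": float(e),
                "distance_to_marker_mm": float(t.distance_to_marker_mm[j]),
            })
    return pd.DataFrame(rows)
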