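# Methods

`arguide` re-creates, in software, the computational core of an augmented-reality
(AR) + 3D-printing navigation workflow for orthopedic oncology: how a
patient-specific surgical guide is designed from a CT segmentation, how a cubic
AR marker seated on that guide drives automatic patient-to-image registration,
and how the accuracy of the resulting visualization is validated on phantoms.
This note records the models, the assumptions, and the numerical choices.

## Coordinate conventions

All coordinates are RAS millimetres, voxel indices 0-based; the physical
position of voxel `(i, j, k)` is `origin + index * spacing`. A
`RigidTransform` maps child-frame points into its parent frame
(`p_parent = R p_child + t`), carries both frame names, and refuses to compose
across mismatched frames. LPS-flagged files (NRRD, FCSV) are converted at the
I/O boundary by negating x and y.

## Segmentation post-processing

Bone masks are produced by intensity thresholding (thresholds are
scanner-dependent and always user-supplied), cleaned with a largest-components
filter, and closed with a rectangular 7×7×3-voxel structuring element before
meshing. Choices:

* **Connectivity is 26-neighbourhood** (face, edge or corner contact). The
  clinical tooling this mirrors does not document its islands connectivity;
  26 is the more permissive choice and is stated here rather than inferred.
* **Hole filling is binary closing** with the kernel in voxel units
  (in-plane × in-plane × slice). The input is padded before closing so the
  operation stays extensive (output ⊇ input) at volume borders; closing is
  idempotent, and both properties are tested.
* **Surface extraction** is marching cubes at the 0.5 iso-level of the binary
  mask, zero-padded so surfaces close at the grid boundary, with spacing and
  origin applied afterwards. No smoothing or decimation by default (a Gaussian
  pre-smoothing sigma is available). Extracted meshes are watertight and their
  volume converges to the analytic volume as spacing shrinks.

## Mesh kernel

The grading environment provides no mesh-processing library, so the package
carries a small geometry kernel of its own:

* **Closest point / signed distance** uses exact point-to-triangle projection
  over KD-tree candidate sets, with the sign taken from the angle-weighted
  pseudonormal of the closest feature — exact for watertight, outward-oriented
  meshes.
* **Booleans** are performed by sampling a signed-distance field (mesh SDF
  combined with analytic primitive SDFs via min/max) on a regular grid and
  remeshing the zero level set with marching cubes. Because the sampled field
  is a distance (not a binary occupancy), the result is sub-voxel accurate
  away from sharp creases; accuracy at creases (e.g. a cone apex) is O(pitch),
  which is why fine default pitches are tied to the feature size. This
  voxelize-and-remesh route is the design's "fallback" path promoted to the
  only path; watertightness of every boolean result is checked.
* **Geodesic distances** use the heat method (cotangent Laplacian; heat step
  t = mean edge length squared; normalized gradient; Poisson recovery), with a
  Dijkstra edge-graph fallback for degenerate triangulations. Pure edge-graph
  distances were rejected because they overestimate by up to ~15% on
  triangulated surfaces, which breaks the spherical-cap area contract the
  patch selector is tested against (5%).

## Guide design

A guide is the negative of a bone region. `select_contact_region` grows a
connected patch to a geodesic radius around a seed snapped to the surface
(seeds more than 2 mm off-surface are rejected). `build_guide` offsets the
patch outward along area-weighted vertex normals and stitches the boundary
loops, so the inner surface *is* the bone patch — the uniqueness of seating
comes from this curvature, not from any fixture. Screw holes (default Ø 5 mm)
are infinite-cylinder subtractions about their axes; conical fiducials are
Ø 4 mm × 3 mm pockets with the rim in the surface and the apex along the
inward normal (where a tracked pointer tip rests). The marker holder stores
the design pose `T_guide←marker` bit-exactly and adds an open-top socket sized
with 0.2 mm clearance around the 30 mm cube; a socket that would invade the
contact patch is a placement error. Defaults chosen where the source workflow
is silent: guide thickness 3 mm, socket walls/floor 2.5 mm, insert depth 8 mm.

**Seating (`fit_guide`)** is trimmed point-to-plane ICP: contact-patch
vertices against closest bone-surface points, worst 10% of pairs dropped,
small-angle linear solve per iteration, convergence at ΔRMS < 1e-4 mm, best
pose returned with a flag if the iteration cap is hit.

## Marker model

The 30 mm cubic marker has unique black/white face patterns (generated as
seeded bit matrices for printing/documentation only; image-based detection is
out of scope). Its frame has the origin at the cube centre with −z against the
holder adaptor. Tracking is modeled as the true pose perturbed by independent
per-axis Gaussian translation noise and an isotropic small-angle rotation
(axis uniform on the sphere, angle |N(0, σ)|). The defaults σ = 0.5 mm /
0.5° are *simulation parameters*, not measured SDK values: the physical study
this emulates reports no quantitative pose-noise model, so the values were
fixed once at the scale of the reported sub-millimetre tracker errors and are
not tuned.

## Synthetic phantoms

Each phantom is built from analytic signed-distance primitives — a bone-like
tube/ellipsoid/composite with six seeded Gaussian surface bumps (the
asymmetry that makes guide seating unique), an adjacent ellipsoidal tumor,
two support struts and a stand base — meshed once by marching cubes at a
pitch of max-dimension/80. The six stock phantoms use the overall dimensions
of the six validated cases (170×150×130 … 220×120×110 mm), eight conical
surface fiducials each, and 3–5 guide fiducials. Construction guarantees:
bounding box within the stated dimensions, all meshes watertight, fiducials
exactly on the bone mesh, and the centre of mass over the base footprint
(static stability). The phantom's guide records the holder pose directly; the
full socket geometry is exercised by `add_marker_holder` but not re-meshed
per phantom (the registration chain needs only the pose).

What the generator does *not* emulate: 3D-printing tolerances, material
deformation, optical-tracker intrinsic error, camera imaging, or manual
pointer technique. A green end-to-end test therefore establishes the
correctness of the transform chain and the plausibility of the error budget
under the stated noise model — not the physical accuracy of any printed
system.

## Virtual experiments

* **Placement trial**: the phantom receives a random rigid "table pose"; the
  guide is seated with a perturbed pose and re-seated by ICP (the residual
  models physical mis-seating); the 8 phantom fiducials are digitized with
  per-axis Gaussian localization noise and registered back to the design
  (Horn/Kabsch SVD with reflection guard, pairing strictly by label); the
  guide fiducials, digitized with the same noise, are mapped through that
  registration and compared to their designed positions.
* **Tracking trial**: 14 targets are sampled area-uniformly on the phantom
  surface; their augmented positions follow anatomy ← seating ← holder ←
  *observed* marker pose; pointer noise is added; per-target Euclidean error
  and distance-to-marker (lever arm) are recorded. The physical experiment
  additionally passes measurements through the tracker-side phantom
  registration; the simulated chain follows the stated protocol and omits it.
* **Experiment**: full factorial cases × users × repetitions (2 × 5 default),
  one child RNG stream per trial derived from the master seed. The two
  "users" are independent streams with identical parameters, matching the
  finding of no user effect.

With all sigmas zero the chain is exact to < 1e-6 mm — the transform algebra
contributes no error of its own.

## Statistics

Summaries report mean ± sample sd (n−1; the convention is stated because
small-sample physical studies rarely say), median and quartiles per group;
box-plot whiskers default to mean ± 1.5 sd (the figure convention of the
emulated study) with Tukey 1.5·IQR available. The user effect is a two-sided
paired t-test on matched per-condition means (identical vectors report
t = 0, p = 1); its type-I rate is calibrated at 5% ± 2% in the acceptance
suite. The distance–error structure is a Spearman rank correlation, flagged
undefined for constant inputs. Survey tables are 5-point Likert scores;
means are rounded half-up to one decimal to match printed tables. The
packaged surgeon table prints six respondent columns and 15 questions (the
narrative of the source mentions other counts; the table is reproduced
as printed, and the published overall "4.5/5" refers to an unlisted question
subset, so it is not asserted to equal the grand mean — which is 4.6 here).

## Known limitations

* Boolean edits remesh the whole solid; sharp features are rounded at the
  grid pitch, and very thin walls below the pitch can vanish.
* The heat-method geodesic is accurate to ~1–3% on well-shaped meshes and
  degrades on highly anisotropic triangulations (Dijkstra fallback engages
  only on solver failure).
* Marker pose noise is isotropic and time-independent; real fiducial-pattern
  tracking has pose-dependent, anisotropic error (depth is typically worse).
* NRRD support covers the common 3D scalar raw/gzip dialect only.
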