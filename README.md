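# arguide

Surgical-guide design and AR navigation-accuracy simulation for orthopedic
oncology.

In image-guided tumor surgery, a **patient-specific surgical guide** is a
printed tool whose contact surface is the negative of a bone region, so it
seats in exactly one position on the patient's anatomy. If that guide also
carries a holder for a **cubic AR marker**, a phone camera that tracks the
marker immediately knows where the patient is: the rigid chain

```
T_anatomy←marker = T_anatomy←guide · T_guide←marker
```

turns marker detection into automatic patient-to-image registration, and
virtual models (tumor, cutting planes) can be overlaid on the surgical field
with no manual landmarking. `arguide` implements the computational core of
that workflow end to end, for engineers and researchers who want to design
such guides, budget their navigation error, or reproduce the validation
protocol virtually:

* **imaging** — CT mask post-processing (thresholding, largest-component
  filtering, 7×7×3 morphological closing) and watertight surface extraction;
  NRRD/NIfTI in, STL/PLY out, everything RAS millimetres.
* **guide_design** — geodesic contact-patch selection, negative extrusion into
  a watertight guide body, Ø 5 mm screw holes, Ø 4 mm × 3 mm conical
  fiducial pockets, the marker-holder socket, bone-fragment extraction, and
  trimmed point-to-plane ICP seating (`fit_guide`).
* **registration** — rigid-transform algebra with named frames, closed-form
  point-based registration (SVD with reflection guard, pairing by label),
  fiducial registration error (FRE) and target errors.
* **marker** — the 30 mm cube geometry, face visibility under occlusion, and
  a seeded noisy-pose stand-in for the tracking SDK.
* **phantom** — six synthetic validation phantoms (bone + tumor + supports +
  base, 8 conical surface fiducials, seated guide with 3–5 fiducials) and the
  two virtual experiments: guide **placement** trials and AR **tracking**
  trials, run as a full cases × users × repetitions design.
* **evaluation** — grouped error summaries (mean ± sd, quartiles, ±1.5 sd
  whiskers), the paired user-effect t-test, distance–error rank correlation,
  and 5-point Likert survey summarization (printed survey tables ship as
  fixtures in `arguide.datasets`).
* **io / cli** — STL/PLY/NRRD/NIfTI/FCSV readers and writers, per-case bundle
  directories, and an `arguide` command with `segment`, `design-guide`,
  `make-phantom`, `simulate`, `evaluate`, `survey` subcommands.

## Worked example

Simulate the full validation experiment — six phantoms at their stated sizes,
two users, five repetitions, 14 surface targets per trial, with 0.5 mm /
0.5° seating and marker-pose noise and 0.5 mm per-axis pointer noise:

```python
from arguide import (default_phantom_specs, generate_phantom, run_experiment,
                     TrackingNoise, trials_to_dataframe, summarize_errors,
                     paired_user_test)

phantoms = [generate_phantom(s) for s in default_phantom_specs()]
trials = run_experiment(phantoms, users=2, reps=5, noise=TrackingNoise(),
                        kind="tracking", seed=1)
df = trials_to_dataframe(trials)
print(f"overall: {df.error_mm.mean():.2f} +/- {df.error_mm.std(ddof=1):.2f} mm")
print(summarize_errors(df, ("case",)).table[["case", "mean_mm", "sd_mm"]].round(2))
```

prints

```
overall: 1.26 +/- 0.55 mm
        case  mean_mm  sd_mm
0  AR3DP0002     1.17   0.54
1  AR3DP0003     1.20   0.51
2  AR3DP0004     1.32   0.57
3  AR3DP0005     1.12   0.47
4  AR3DP0006     1.34   0.56
5  AR3DP0007     1.40   0.61
```

The grand mean is the simulated **AR tracking error**: every target passed
through guide mis-seating, the holder pose, a noisy marker observation and
the pointer touch. The largest phantoms show the largest means — the
lever-arm effect of rotational marker noise, which the package quantifies as
a positive Spearman correlation between target-to-marker distance and error
(`distance_error_correlation(df)` → rho = 0.13, p ≈ 1e-4 here). Comparing
the two simulated users per case with `paired_user_test` gives t = 0.01,
p = 0.99: no user effect, as designed. With every sigma at zero the same
chain reports errors below 1e-6 mm — the registration algebra itself is
exact.

The same experiment from the shell:

```bash
arguide simulate --kind tracking --users 2 --reps 5 --seed 1 --out tracking.csv
arguide evaluate --trials tracking.csv --group-by case
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time: the per-question and per-respondent
averages of the packaged surgeon and patient survey tables (targets t1–t4),
and the overall mean visualization error of the full simulated tracking
experiment described above (target t5, in mm). The JSON maps each target id
to its measured value and the problem size used.
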