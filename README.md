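# tonofem

Finite-element simulation of corneal applanation tonometry.

Tonometry estimates the intraocular pressure (IOP) of the eye by pressing an
instrument against the cornea and measuring the mechanical response. `tonofem`
rebuilds that measurement *in silico*: a parametric, asymmetric cornea–sclera
shell with published anatomical dimensions is pressurised to a clinical IOP
and indented by a rigid flat-ended cylindrical probe, and the package computes
the **applanation force** as a function of the probe's plunging depth and the
IOP, together with the deformation and von Mises stress fields. The intended
users are ocular-biomechanics researchers and instrument designers who need
force–depth–IOP tables (for example as feedback curves for tonometer
prototypes) with a fully open, verifiable computational chain.

## Model

* **Geometry.** Each of the four key meridians (superior / inferior / nasal /
  temporal) is an exact arc-spline: anterior corneal arc (radius 7.75 mm),
  a corneoscleral kink at the quadrant-specific junction angle
  (178.1° / 177.7° / 173.9° / 177.0°), a 1.5 mm limbal transition arc, and a
  scleral arc (radius 11.2 mm) closing at the posterior pole at the 22.7 mm
  axial length. The four profiles are lofted by periodic trigonometric
  interpolation in azimuth. Corneal thickness blends 0.52 → 0.67 mm from apex
  to limbus; the sclera is 0.317 mm thick (optional +0.298 mm choroid).
* **Mechanics.** Small-strain isotropic linear elasticity
  (cornea E = 0.2 MPa, ν = 0.43; sclera and limbus E = 2 MPa, ν = 0.4) on a
  structured hexahedral mesh (trilinear with selective reduced integration, or
  serendipity-quadratic), with the IOP applied as a consistent pressure load
  on the closed inner surface (1 mmHg = 133.322 Pa) and rigid-body motion
  removed by six averaged "remote displacement zero" constraints on the outer
  sclera.
* **Contact.** The probe is an analytic rigid surface advancing along the
  apex axis. Non-penetration is enforced by a mortar-style penalty on
  weighted-average gaps clipped to the probe footprint, iterated over the
  active set at each of (by default) ten displacement increments. Each solve
  is performed exactly by low-rank block elimination against a single matrix
  factorisation, so one factorisation serves an entire force–depth–IOP sweep.
* **Verification.** Closed-form oracles gate the solver: membrane stress of a
  pressurised spherical shell (σ = pR/2t) and the Boussinesq rigid flat punch
  on an elastic half-space (F = 2aEδ/(1−ν²)), the latter on a cylindrical
  fixture with crack-tip-style mesh grading into the punch rim.

## Worked example

```python
from tonofem import (LoadCase, PROBE_PRESETS, build_eye_shell,
                     default_materials, solve_indentation, sweep_shell_mesh)

mesh = sweep_shell_mesh(build_eye_shell(), 24, 20, 2, order=2)
case = LoadCase(iop_mmhg=20.0, probe=PROBE_PRESETS["standard"],
                target_depth=0.5)
res = solve_indentation(mesh, default_materials(), case)
print(f"applanation force: {res.reaction_force:.4f} N")
print(f"max deformation:   {res.max_total_deformation[0]:.3f} mm")
print(f"max von Mises:     {res.max_von_mises[0]:.4f} MPa "
      f"in {res.max_von_mises[1]}")
```

prints

```
applanation force: 0.0441 N
max deformation:   0.574 mm
max von Mises:     0.0708 MPa in junction_nasal
```

i.e. flattening the cornea of a 20 mmHg eye by 0.5 mm with the 1.7 mm probe
takes about 44 mN; the largest displacement (0.57 mm, exceeding the imposed
depth because the cornea bulges at the probe rim and the globe inflates) sits
at the contact rim, and the stress concentrates at the corneoscleral junction
of the nasal quadrant — the quadrant with the sharpest junction angle.

The same study from the shell:

```bash
tonofem sweep --outdir out          # 15-point depth x IOP table + fits
tonofem verify                      # closed-form oracle suite
tonofem build-mesh --resolution reference --out eye.vtu
```

`out/sweep.csv` holds the force/deformation/stress table, and
`out/relations.json` the per-IOP linear force–depth fits (R² > 0.999: the
force varies linearly with plunging depth) and the fitted IOP sensitivity of
the force, about 5 mN per 5 mmHg at the default grid.

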