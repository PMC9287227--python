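# Methods

This note records the model behind `tonofem`, the numerical choices, and what
the verification fixtures do and do not establish. Units are mm–N–MPa
throughout; IOP is entered in mmHg and converted at the metrological value
1 mmHg = 133.322387 Pa (so 20 mmHg = 2.66645 kPa).

## Eye geometry

The wall (cornea + sclera) is a closed shell built from published
anatomical dimensions: corneal anterior radius of curvature 7.75 mm, central
and peripheral corneal thickness 0.52 / 0.67 mm, scleral radius 11.2 mm and
thickness 0.317 mm (choroid 0.298 mm, off by default since only corneal and
scleral elastic constants are given), axial length 22.7 mm, and
quadrant-specific corneoscleral junction angles (superior 178.1°, inferior
177.7°, nasal 173.9°, temporal 177.0°). The coordinate origin is the corneal
apex with +x toward the posterior pole — the probe travel direction.

**Meridian construction.** A meridian cross-section cannot consist of just
two circular arcs at these dimensions: if the scleral arc (R = 11.2) is to
pass through the posterior pole of a 22.7 mm globe and meet the corneal arc
(R = 7.75), the kink between them is at least ~9°, whereas the measured
junction angles imply kinks of only 1.9–6.1°. A real limbus is a transition
zone, so each profile is an exact arc-spline of three segments: the corneal
arc, a sharp kink at the printed junction angle, a 1.5 mm transition arc
whose signed radius is solved so that it joins tangentially onto the scleral
arc, and the scleral arc itself, centred on the axis so the profile closes
orthogonally (smoothly) at the posterior pole. The solved transition is
slightly concave for angles below 180° — an external scleral sulcus, which is
anatomically reasonable. All printed dimensions and angles are reproduced
exactly; the junction kink is a true tangent discontinuity of the outer
surface.

**Loft.** The four profiles sit at azimuths 0° (nasal), 90° (superior), 180°
(temporal), 270° (inferior). Corresponding meridian stations are interpolated
azimuthally with the four-term periodic trigonometric interpolant
a₀ + a₁cosθ + b₁sinθ + a₂cos2θ, which reproduces each key slice exactly, is
smooth and periodic, and reduces to a surface of revolution when the four
profiles coincide. All profiles share the apex and posterior-pole points, so
the lofted surfaces are watertight by construction. Thickness varies linearly
in arc length across the cornea (0.52 → 0.67), blends smoothly (smoothstep)
to the scleral value across the 1.5 mm limbal band, and is constant beyond;
the inner surface is the exact normal offset of the outer arc-spline.

## Discretisation

The shell is swept into a structured hexahedral mesh in (meridian, azimuth,
through-wall) coordinates, with elements collapsing to wedges at the two
poles. Meridian stations are graded toward the apex (the contact region);
the corneal kink and the limbal band edges always lie on mesh lines, giving
the nine-region partition (1 cornea, 4 limbal junction, 4 scleral quadrants)
used for material assignment and reporting. Element types: trilinear
hexahedra with selective reduced integration of the volumetric (λ) term —
full integration locks visibly at ν = 0.43–0.48 — or 20-node serendipity
hexahedra with 3×3×3 quadrature for bending-dominated accuracy. Resolution
presets: `coarse` (16×16×2, trilinear) for tests, `medium` (24×20×2,
quadratic), and `paper` (56×52×2, quadratic; ≈31.6k nodes / 5.8k elements),
chosen to sit within ±50% of the reference study's 58,999 nodes / 11,613
elements. (The reference's quoted "average element size 1.9816 mm" is not
reproducible as an edge statistic: that size cannot tile a ~0.3–0.7 mm-thick
wall at that element count; it can only be a mesher size setting.)

Force–depth results converge with refinement: the quadratic `medium` and
`paper` presets agree to well under 1%, while trilinear meshes approach the
same values from above (≈ +9% at 48×40×2).

## Mechanics and loading

Small-strain isotropic linear elasticity with cornea E = 0.2 MPa, ν = 0.43
and sclera E = 2 MPa, ν = 0.4; the limbal junction band uses scleral
properties (only two tissues' constants are published; the assignment is
configurable). Densities are carried but unused (static analysis); the steel
probe is never meshed — its modulus is ~10⁶ × the cornea's, so it is treated
as rigid.

The IOP acts as a uniform consistent pressure load on the closed inner
surface, on the reference configuration (dead load, no follower stiffness —
consistent with the small-strain setting). Because the surface is closed, the
load's resultant force and moment vanish identically.

Rigid-body motion of the globe is removed in one of two ways:
`remote-rigid-body` (default) imposes six averaged constraints — zero mean
translation and zero mean infinitesimal rotation of the outer scleral
surface — through Lagrange multipliers, leaving the sclera free to deform
(a deformable attachment, mimicking the orbit); `posterior-patch` fixes all
DOFs on the posterior scleral cap (polar angle > 140° from the apex). By
Saint-Venant's principle the two differ by < 5% in the applanation force.
Note the averaged constraint fixes the *mean* of the constraint set, so a
uniform inflation field acquires a compensating rigid translation; field
post-processing that needs the pure deformation (e.g. the sphere-expansion
oracle) removes the best-fit rigid motion first.

## Contact

The probe face is analytic: flat within its radius (optionally edge-filleted)
at axial position x = depth, where depth is the probe travel measured from
the undeformed apex plane — the CAD convention of the reference setup, in
which the probe initially touches the unpressurised cornea. The IOP is
applied first (one linear step); the probe then advances in equal increments
(default 10) at constant IOP.

Non-penetration is enforced by a mortar-style penalty: the contact
constraints live at the Lagrange grid points of the candidate surface faces,
each testing the *weighted average* gap over its positive piecewise-bilinear
hat function, with all integrals clipped to the probe footprint. Because the
hats are a partition of unity, the mortar weights sum exactly to the
footprint area; point-wise gap checks instead mis-estimate the contact patch
by O(mesh spacing), which at a flat-punch rim biases the force by 10–20%.
The penalty stiffness per constraint is `penalty_scale · E_cornea · (mortar
area / central corneal thickness)` with `penalty_scale = 1e6`, floored for
sliver overlaps at the rim; this keeps the residual penetration below
1e-5 mm (an order of magnitude inside the 1e-4 mm convergence criterion)
while a 10× stiffer penalty changes forces by far less than 1%. On quadratic
meshes the contact operators are built on the bilinear corner sub-surface:
the serendipity shape functions' negative lobes otherwise make the
active-set iteration chatter.

The active set is iterated at each increment until stable; all solves are
exact block eliminations (Woodbury identity) against a single factorisation
of the constrained stiffness (SuperLU in symmetric mode), with the
unit-pressure response and the contact influence columns cached. A full
15-point force–depth–IOP sweep therefore costs one factorisation plus dense
algebra on a few hundred candidate DOFs.

An `updated_geometry` option re-assembles the stiffness (and pressure load)
on the deformed configuration in a fixed-point loop. It adds first-order
geometric updating but not stress-stiffening, and is not the default: the
reference analysis is read as a geometrically linear static solve, and the
default keeps contact as the only nonlinearity.

## Stress and deformation reporting

Stresses are computed at quadrature points and reported two ways: averaged
per element (robust, used for field export), and extrapolated to nodes via
the tensor-product Lagrange interpolant with averaging across adjacent
elements — the convention interactive post-processors use for contour
maxima, and the one used for "maximum von Mises" summaries here. On the
pressurised sphere fixture the nodal maximum reproduces the Lamé bore stress
within 1.4%, where element averages sit ~7% low. "Total deformation" is the
Euclidean norm of nodal displacement. The flat punch's rim stress is singular
in the continuum limit, so reported maxima are mesh-regularised; stress
summaries are tied to the fixed `paper` preset.

## Verification fixtures

Two closed forms gate the solver (`tonofem verify`, and the pre-gate of
`scripts/acceptance.py`):

* **Pressurised spherical shell** (scleral dimensions R = 11.2, t = 0.317,
  p = 20 mmHg): FE membrane hoop stress within 2% of the thin-wall value
  evaluated at the pressurised-surface radius, p(R − t/2)/2t. At these
  proportions t/R ≈ 2.8%, which is exactly the gap between the mid-surface
  thin-wall formula and the exact Lamé wall average — the FE solution
  converges to the Lamé value, so the mid-surface form is the wrong
  comparison at the 2% level. Radial expansion is checked against
  pR²(1−ν)/2tE after removing the best-fit rigid translation.
* **Rigid flat punch** (a = 0.85 mm, corneal constants, δ = 0.1 mm) against
  F = 2aEδ/(1−ν²) within 5%. The fixture is a cylindrical half-space with
  crack-tip-style geometric grading into the punch rim (a node ring exactly
  at r = a, 300 mm domain); on a Cartesian block mesh the rim singularity
  limits force accuracy to ~10% at affordable resolutions, and the block
  variant is kept with that documented tolerance.

## What the model does and does not capture

The synthetic eye reproduces the printed anatomy, the pressurisation, the
frictionless rigid-probe kinematics and the asymmetric quadrant structure.
The computed behaviour matches the reference study qualitatively everywhere
it can be compared: forces are almost perfectly linear in plunging depth
(R² > 0.999) and increase with IOP (≈ 5 mN per 5 mmHg, the same order as the
reported ≈ 4 mN); the maximum deformation exceeds the imposed depth and sits
at the probe rim; the stress concentrates at the corneoscleral junction —
specifically the nasal quadrant, whose junction angle is sharpest.

Quantitatively, the small-strain model overestimates the Goldmann-probe
force magnitudes by roughly 2×. The reference Goldmann series
(0.029–0.040 N over 0.3–0.7 mm) has a slope of only 0.007 N/mm over an
Imbert–Fick-like offset ≈ IOP × probe area, a saturation behaviour
characteristic of a geometrically nonlinear analysis of a flattening shell
(once the cornea is applanated, extra travel adds little elastic force). A
geometrically linear model has a constant contact stiffness (~0.09 N/mm for
the Goldmann probe here) and cannot reproduce that plateau — at the smallest
depth the two agree far better than at the largest. The 1.7 mm-probe
force–depth slope, by contrast, agrees with the reference to ~13%, and its
maximum force (0.056 N vs ≈ 0.045 N) to ~25%. Aqueous humour flow, the
IOP rise caused by indentation-displaced volume, viscoelasticity and tissue
nonlinearity are outside scope, as in the reference analysis. The ~1.5 mm
limbal transition band also smooths the junction stress concentration
relative to a sharp CAD kink, so peak von Mises values here (~0.086 MPa at
the reference preset) are below the ~0.2 MPa of the reference contour plots,
though in the same region.
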