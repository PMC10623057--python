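# Methods

## Model

The cornea is idealized as a thin, flat, linear-elastic square plate of
60 × 60 mm under plane stress, containing a single traction-free incision
(crack) of total arc length 2a = 2.2 mm at its center. Three incision
families are parameterized:

- **straight** — a horizontal segment;
- **chevron** — two straight arms of length a meeting at an apex with included
  angle α ∈ [120°, 180°]; α = 180° degenerates continuously to straight;
- **frown** — a circular arc of arc length 2a subtending a central angle
  β ∈ (0°, 50°]; β → 0 degenerates to straight. The arc bows upward; for the
  isotropic material a frown and a smile are mechanically identical, so one
  orientation is fixed by convention (apex/bow up, midpoint at the plate
  center).

Loading is a uniform outward normal traction σ₀ on all four plate edges
(equibiaxial tension). For the straight crack the edge-parallel component
contributes no opening and no stress intensity, so this coincides with the
classic remote-tension mode I configuration; for kinked and curved incisions
the biaxial component matters and is retained. The crack faces carry no
contact model: the loads used here only ever open the seam, and any computed
interpenetration is flagged as an invalid load direction.

Insertion of the IOL injector is represented kinematically: the applied load
is scaled so that the seam opening at the incision midpoint (the chevron apex
or arc midpoint) equals the injector diameter d = 1.73 mm. Because the
problem is linear this calibration is exact — one solve at a reference load
fixes the scale, a confirming solve verifies it. The maximum opening along
the seam is recorded alongside; for every converged case here it coincides
with the midpoint value to high accuracy.

Fracture onset is judged by the Griffith energy-release-rate criterion: the
incision tears further when G > G_c, with G the J-integral at a tip (equal to
the energy release rate in linear elasticity) and G_c a measured toughness.
The boundary case G = G_c is classified as non-tearing.

### Material constants

| constant | default | provenance |
|---|---|---|
| E | 9.82 MPa | porcine cornea, 3 mm/min strain rate |
| G_c | 5.40 kJ/m² | same source and strain rate |
| ν | 0.49 | **not** a measured corneal value: near-incompressible soft-tissue default, configurable; the straight-crack G and opening are ν-independent in the large-plate limit, and the chevron/frown calibrated G changes by < 0.1% between ν = 0.30 and 0.49 |
| d | 1.73 mm | mean diameter of six commercial IOL injectors |

For the orthotropy study the moduli pairs (E_x, E_y) follow the published
table verbatim, including its η = 0.75 row whose printed moduli
(9.82, 14.73 MPa) actually have ratio 2/3 — the row is carried with its
printed label and moduli rather than "corrected". E_y is the modulus along
the vertical symmetry axis of the incision. Only the ratio is physically
motivated; the auxiliary constants default to ν_xy = ν·√(E_x/E_y), capped at
95% of the thermodynamic stability limit, and
G_xy = √(E_x·E_y) / (2(1+√(ν_xy ν_yx))) (a standard geometric-mean estimate).
Both are configurable, and only *orderings* (not values) should be read off
the non-isotropic results.

## Discretization

### Mesh

The mesher is a single structured construction, not a general-purpose
unstructured mesher: a layered O-grid wrapped around the incision.

- **Layer 0** is the incision itself, traversed along both faces. Interior
  polyline vertices are duplicated into coincident seam pairs; each tip is a
  single node. Crack vertices are graded geometrically toward the tips
  (innermost spacing r_inner = a/50) and capped at a/24 in the middle, with
  the midpoint always a vertex.
- **Layers 1..K** are closed "stadium" curves: normal offsets of the
  tip-to-tip chord at distance t, with circular caps of radius t around each
  tip, plus the incision's deviation from the chord decaying as
  exp(−4(t/a)²). The Gaussian decay keeps 1 − w = O(t²), so the innermost
  layers stay parallel to the crack faces even for strongly kinked chevrons.
- Between layer 0 and layer 1 the cap segments collapse, so quadrilaterals
  degenerate into a fan of `n_spokes` triangles at each tip — the classic
  spider-web tip pattern produced by a sweeping strategy. All other elements
  are bilinear quadrilaterals.
- The first `n_rings` (default 10) layer radii grow geometrically
  (ratio 1.35) and define the contour-integral rings; subsequent layers
  coarsen (growth 1.15, thickness capped by `far_field_size` = 2 mm) and the
  last `n_blend` = 16 layers blend onto the exact square boundary by radial
  interpolation, with the four nearest nodes snapped onto the plate corners.
  The blend schedule ends at (plate half-width − half-chord) so every
  pre-final layer lies strictly inside the plate.

Mesh validity is enforced, not assumed: coincident seam pairs, uniformly
oriented element areas (mixed signs abort with a "tangled layers" error),
strictly positive corner Jacobians for every quadrilateral, conforming edge
usage, and exact tiling of the plate area. Contour rings are grown from each
tip by node connectivity (ring 1 = all elements containing the tip node —
the triangle fan plus the two face quadrilaterals; ring k = new neighbors of
rings < k), which maps one-to-one onto the per-ring contour-integral
evaluation and never crosses the seam because the two faces carry distinct
node ids.

Default resolution is ≈ 8 900 elements per case and was fixed once against
the straight-crack closed form: fixed-load G within 0.3%, midpoint opening
within 0.5%, ring 4–10 scatter ≈ 0.2%, calibrated G within 0.9% of
πEd²/(16a). Halving r_inner and the far-field size changes G by < 1% (the
grid-independence check). Each full case (mesh, solve, contour integrals)
takes well under a second on one CPU; the full chevron sweep runs in
≈ 15 s and the 5 × 4 orthotropy table in ≈ 15 s.

### Solver

Fully integrated bilinear quadrilaterals (2 × 2 Gauss) and constant-strain
triangles, assembled sparse and solved directly. No reduced integration and
hence no hourglass control is needed. Rigid-body motion is removed by a
mirror-symmetric gauge — u_x pinned at the top-center and bottom-center
boundary nodes, u_y at top-center — which is exactly compatible with the
x-mirror-symmetric solution, so the symmetry of the displacement field is
preserved to solver precision (a plain corner- or edge-point clamp would
leave it only up to a rigid translation). Work–energy balance
(U = ½∮ t·u ds) is checked on every solve at 10⁻⁶ relative; the uncracked
(merged-seam) plate reproduces the homogeneous equibiaxial state to 10⁻⁹
(patch test), for both isotropic and orthotropic stiffness.

### Energy release rate

G is evaluated in equivalent-domain (area) form,

J = ∫_A [σᵢⱼ (e·∇)uᵢ ∂q/∂xⱼ − W (e·∇q)] dA,

with the virtual-extension direction e the local crack tangent at the tip
(self-similar straight-ahead extension — at a kinked or curved tip the
single J absorbs the full mixed-mode energy flux; no mode decomposition is
attempted). The weight q is 1 on the nodes interior to the previous contour
region and 0 outside, so ∇q is supported on one element ring at a time —
the area analogue of nested line contours. Rings 1–3 are discarded as
tip-affected; the reported G is the arithmetic mean of rings 4–10 and their
relative standard deviation is the convergence diagnostic (flagged above
2%). No curvature correction terms are included: the outermost ring radius
(≈ 0.33 mm) is small against the shallowest arc radius considered
(≈ 2.5 mm at β = 50°).

Verification chain for the integral: Griffith closed form on the center
crack to < 1%; left/right tip agreement to < 0.5% (exactly 0 for symmetric
shapes by construction); exact quadratic load scaling; error on a
merged-seam mesh.

## Protocols

- **Sweeps** step α (120°–180°) or β (5°–50°) in 5° increments with a 1°
  refinement pass around the detected minimum, each angle at its own
  calibrated load. The Griffith crossing angle is linearly interpolated
  between the grid points bracketing G = G_c.
- **Critical length** inverts G(2a) = G_c by Brent's method with per-iterate
  remeshing and recalibration (tolerance 1 µm on 2a); G decreases with
  length at fixed opening (closed form G = πEd²/(16a) for the straight
  incision, reproduced by the FE inversion within 1%).
- **Shape comparison** reports (G_straight − G_shape)/G_straight × 100 for
  the best chevron and best frown.

## What the generated inputs do and do not emulate

The mesher is the package's synthetic-input generator: its defaults *are*
the study conditions (plate, incision length, load style, material, injector
diameter). It does not emulate corneal surface curvature, the 3D
sclero-corneal tunnel architecture, nonlinear or viscoelastic constitutive
response (strain-rate dependence is baked into the single (E, G_c) pair), or
crack-face contact. Passing tests therefore validate the 2D linear-elastic
idealization, not cornea-specific geometry beyond it.

## Known limitations and discrepancies

- The published account of this configuration reports a few results that a
  converged linear-elastic model does not reproduce. Our solution matches
  the published fixed-load chevron-150° pair (σ₀ = 3.95 MPa → G = 5.12 kJ/m²)
  to 0.2%, yet our converged opening per unit load at the chevron apex is
  ≈ 5% smaller, so our calibrated load is 4.15 MPa rather than 3.95 MPa.
  This is insensitive to ν (0.30–0.49) and to mesh refinement. Relatedly,
  our calibrated G(α) is monotone (minimal at the straight limit α = 180°)
  and G(β) decreases mildly with β, whereas the published sweeps show a
  ≈ 2–3% dip at α = 170°, a sharp minimum at β = 6°, and G rising through
  G_c at β = 35°. We attribute the difference to discretization of the
  reference computation (reduced-integration elements; ad-hoc node repairs
  on the symmetry axis, exactly where the calibration opening is measured).
  The package reports its own converged values; the acceptance suite states
  the published numbers and marks the irreproducible ones as failures rather
  than tuning toward them.
- Sensitivity embedded in that choice: a ±5% bias in the calibration opening
  moves every calibrated G by ∓10%, which spans most of the disagreements
  above.
- The frown/smile distinction under anisotropy, corneal curvature, and
  hyperelastic constitutive laws are out of scope.
- High-aspect far-field elements above and below the incision (the price of
  the purely structured O-grid) cost some far-field accuracy per node; this
  is compensated by the radial layer refinement and verified by the patch
  and grid-independence tests.
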