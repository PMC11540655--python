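# Methods

`brachysim` simulates the tissue mechanics of high-dose-rate (HDR) prostate
brachytherapy: two thin anchor needles followed by seventeen catheter-needles
are advanced transperineally into a prostate embedded in softer surrounding
tissue, and the resulting gland deformation is quantified by Dice overlap of
voxelised shapes and by in-plane displacement statistics. This note records
the model, the numerical scheme, the synthetic phantom that stands in for
patient imaging, and the design decisions taken where the problem left the
choice open.

## Continuum model

Tissue is a near-incompressible Neo-Hookean solid in the decoupled (J-split)
form

    W(F) = mu/2 (J^(-2/3) tr(FᵀF) - 3) + kappa/2 (J - 1)²,   J = det F,

with the first Piola–Kirchhoff stress P = ∂W/∂F assembled in a total-Lagrangian
setting (all kinematics referred to the reference configuration). Defaults:
prostate E = 25 kPa, surrounding tissue E = 10 kPa, ν = 0.49,
ρ = 1000 kg/m³ — mid-range prostate elastography values. The absolute moduli
matter little for a displacement-driven procedure; the contrast and
near-incompressibility are what shape the fields. Anisotropy, viscoelasticity
and alternative hyperelastic laws are out of scope.

Units: mm, s, kPa, kg/m³. In these units nodal force (kPa·mm² = mN) divided
by nodal mass (kg) is directly an acceleration in mm/s².

## Discretisation

The domain is a point cloud on a regular lattice (spacing h) with
background-cell quadrature and modified-moving-least-squares (MMLS) shape
functions: a quadratic monomial basis whose six second-order coefficients
carry a small diagonal penalty, so the moment matrix stays invertible on
sparse or coplanar supports while quadratic fields are still recovered on
well-populated ones. The weight kernel is regularised-singular,
w(r) = 1/((r/h)² + 1e-8), which makes the shape functions interpolating to
~1e-6 at the nodes; Dirichlet values are therefore imposed directly on nodal
parameters. Two non-obvious choices:

- The quadratic penalty is scaled by the support's weight sum
  (μ_p = 1e-8 · Σw) rather than by a frame-dependent quantity such as the
  moment-matrix trace. The penalised fit is then invariant under translation
  of the local frame, which makes the shape functions exactly differentiable;
  the tabulated gradients agree with central finite differences to ~1e-9.
- Supports come from a radius search at 2× the spacing, locally enlarged
  ×1.25 (at most 5 times) until at least 11 nodes (basis size + 1) support
  each evaluation point.

Quadrature is per background cell, in two qualities:

- `cell` (default for the large procedure runs): one point per cell. Cheap,
  but there are fewer cells than nodes, so the discrete operator has a
  near-zero-energy (hourglass) null space. At the procedure tolerances
  (0.5–1 mm displacement scales, relax tolerance 1e-3 mm) the resulting
  noise is immaterial for the reported Dice and displacement statistics, but
  pointwise field properties should not be read off such runs.
- `gauss2`: full 2×2×2 Gauss per cell. Hourglass-free and used for all
  verification statics (patch test, bar compression) and the single-needle
  field-property suite, at 8× the assembly cost.

Nodal masses are lumped by tributary volume: each integration point's mass is
split equally over its 8 nearest nodes (the corners of its cell), which makes
every interior node carry exactly ρh³, keeps masses positive and conserves
total mass to machine precision. Shape-function row-sum lumping is unusable
with the singular-kernel MMLS: row sums deviate from the cell mass by ~10–20%
in the interior and turn negative at corners.

## Explicit dynamics and dynamic relaxation

Time stepping is damped central difference with a CFL bound
dt = 0.5 · h / c_max, c_max the dilatational wave speed over integration
points. Quasi-static states are obtained by dynamic relaxation: stepping
until the maximum nodal displacement increment over a trailing 50-step window
falls below a tolerance (default 1e-3 mm; mid-needle increments use 2.5× that,
the final increment of each needle the full tolerance). Mass-proportional
damping is adapted per window from a Rayleigh-quotient estimate of the
dominant transient mode (Underwood-style adaptive dynamic relaxation), seeded
by a shear-standing-wave estimate of the fundamental frequency and clamped to
[0.05, 50]× the seed. Prescribed-motion increments are ramped linearly over
the first ~50–250 steps of each relaxation to avoid shock transients and
spurious element inversion. During relaxation the nodal density may be scaled
by the local stiffening factor ("mass scaling"), which leaves the
quasi-static limit untouched while keeping dt independent of needle-induced
stiffening; it is disabled in every dynamic-accuracy test.

Meshfree test functions of free nodes do not vanish between the nodes of a
Dirichlet boundary, so a constant-stress state leaves a spurious residual
P·s_i, with s_i = Σ_ip w ∇₀φ_i the discrete divergence of φ_i. For
fully-constrained verification problems (the linear patch test) the solver
subtracts a reaction correction P(node)·s_i — evaluated from the nodal
gradient tabulation and under-relaxed so it tracks the stress
quasi-statically — which cancels the residual exactly for affine fields. The
correction is masked off near traction-free faces, where the uncorrected
surface term is the correct natural boundary condition, and it is not used in
the procedure runs: there the clamped faces are far from the gland and the
correction's stress feedback can destabilise partially-constrained
configurations. Interior accuracy is protected by Saint-Venant decay — the
mid-bar stress in the uniaxial tests matches the closed-form Neo-Hookean
solution to <0.1% without any correction.

## Kinematic needle insertion

Needles are kinematic paths, not deformable bodies. Each advance moves the
tip by Δd (default 2 mm; 3 mm in the scaled-down runs) and prescribes, on
nodes inside the tip's influence region, an axial displacement increment
w·Δd composed with the node's current displacement; dynamic relaxation then
equilibrates the free nodes. The influence region is a capsule of radius
R_inf = 3 mm (≈ 4× the catheter radius) around the trailing R_inf-long
segment of the penetrated path: material moves with the tip while the tip is
near and is released — relaxing against the shaft — once it has passed.
Defining the influence by distance to the whole penetrated path instead would
drag every near-bore node by Δd at every advance, accumulating tens of mm of
displacement near the entry face and inverting the discretisation; distance
to the tip region is also what the clinical picture (tissue sliding along the
shaft) suggests. The radial decay is linear from 1 at the needle surface to 0
at R_inf (an exponential profile is available).

Two further rules:

- Bore nodes (within the needle radius of any placed path) remain constrained
  at their accumulated position while needles are in place.
- The accumulated prescribed drag per node is capped at 2 mm (`max_drag`):
  beyond it the tissue slides along the shaft. Without the cap the drag
  integrates to ~2·R_inf ≈ 6–7 mm per passing needle, which both exceeds the
  displacement scale reported for this procedure and crushes the cells ahead
  of the tip on grids at or below ~3–4 mm spacing.

Anchor effect: after both anchors reach depth, surrounding (non-prostate)
integration points distal to the shallowest anchor tip plane are stiffened
×30 (scale composition by maximum, never by product — overlapping anchor and
catheter stiffening saturates at 30, not 900). Placed catheters stiffen a
2 mm-radius tube around their path by the same factor. Anchors stop at 2/3 of
the prostate extent along the insertion axis; catheters overshoot the distal
prostate boundary by 2 mm.

## Synthetic phantom and needle template

Patient imaging is replaced by an ellipsoidal prostate (default semi-axes
20 × 15 × 15 mm, a ~40 mm gland span) centred in a softer 80 mm cube, nodes
on a regular lattice (default 5 mm spacing), insertion axis +z. All block
faces are clamped except the entry face, which is traction-free (its rim
stays clamped). Needle plans mimic a transperineal template: a square grid
(default 5 mm pitch) over the prostate silhouette; the two anchors (radius
0.5 mm) take the holes nearest the gland centre, catheters (radius 0.75 mm)
the nearest remaining holes. Two built-in insertion orders alternate between
extreme template positions — left-bottom/right-top working inward, or
bottom-right/bottom-left — emulating alternating clinical sequences. Real
segmentations can be substituted through `domain_from_mask` (NIfTI/MHA).

What the phantom does not emulate: bladder/rectum anatomy, probe indentation,
the pre-stressed reference configuration of imaged glands, needle deflection,
and cutting-force physics. Passing tests therefore demonstrate the numerical
correctness and qualitative behaviour of the procedure model, not
patient-specific accuracy.

## Evaluation

The deformed prostate is voxelised by reconstructing a closed surface from
the deformed prostate nodes (alpha-shape over their Delaunay tessellation,
alpha = 2× spacing, convex-hull fallback) and marking voxels whose centres
lie inside or within half a nodal spacing of a region node — the tributary
radius of the outermost nodes, without which the node-hull underestimates the
continuum volume by O(h/2 · area). At 2 mm spacing and 1 mm voxels the
reconstructed ellipsoid volume is within ~1% of (4/3)πabc. Dice coefficients
are always computed on a common cubic domain: the union bounding box of the
two masks inflated to a cube, at the finer voxel size, nearest-neighbour
resampled. In-plane displacement statistics project nodal displacements onto
the plane orthogonal to the insertion axis (the short-axis ultrasound view)
over prostate nodes.

## Problem sizes used in the shipped studies

- Full-procedure run (2 anchors + 17 catheters): 70 mm block at 5 mm spacing,
  3 375 nodes, Δd = 3 mm.
- Paired experiments (anchor ablation; insertion-order comparison): scaled
  phantom (24×18×18 mm gland in a 36 mm block at 3 mm spacing, 2 197 nodes)
  with 2 anchors + 8 catheters per run.
- Single-needle field-property suite: 56 mm block at 4 mm spacing with full
  2×2×2 quadrature.
- Statics verification: 16×16×24 mm bar at 2 mm spacing (1 053 nodes; stubby
  on purpose — a slender bar buckles near 5% compression, invalidating the
  homogeneous uniaxial oracle) and a 20 mm cube for the patch test.

## Known limitations

- Single-point quadrature carries hourglass modes; procedure-scale metrics
  are robust to them but pointwise fields from `cell`-quadrature runs are
  noisy at the ~0.05 mm level.
- Global radial monotonicity of the single-needle displacement field is
  physically false in a confined near-incompressible block: the clamped outer
  boundary drives a weak return circulation whose magnitude peaks off the
  path. Monotone decay holds out to the gland radius.
- The small-strain uniaxial modulus is recovered by a ±1% secant: at a 1%
  strain the Neo-Hookean nominal stress already deviates from E·ε by ~1%, so
  a one-sided comparison conflates model nonlinearity with discretisation
  error.
- The kinematic insertion rule (influence radius, decay, drag cap, bore
  holding) is a plausible, config-exposed model of needle–tissue interaction,
  not a calibrated one.
- The model's sensitivity to the catheter insertion order is somewhat
  stronger than the "marginal" effect one would hope for: the two built-in
  orderings end with gland shapes overlapping at Dice ≈ 0.95 (full 2+17
  procedure; the two displacement fields differ by ~1 mm on average). The
  effect is converged — stable under tighter relaxation tolerances, smaller
  advance increments and finer evaluation voxels — and traces to the
  path-dependence introduced by sequentially stiffening each placed
  catheter's neighbourhood.
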