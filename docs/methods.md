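# Methods

`pcmech` couples a macroscale hexahedral finite-element model of the
Pacinian corpuscle (PC) to microscale fiber-network representative volume
elements (RVEs), and uses it to study how lamellar anisotropy and embedding
depth shape the receptor's response to static skin indentation.

## Model

**Microscale.** Each RVE is a dimensionless unit cube containing a Delaunay
fiber network in a constrained mixture with a compressible neo-Hookean
matrix. A fiber with stretch λ_f carries the axial force

    F = (A/B) (exp(B·E_f) − 1),   E_f = ½(λ_f² − 1),

with A = 114 μN (stiffness scale; also the small-strain slope dF/dE_f at
zero strain), B = 10 (nonlinearity), both fitted by the upstream multiscale
framework to uniaxial dermis data. Fibers carry compression through the
same law (no buckling model). The macroscopic deformation gradient F is
imposed as an affine displacement of the boundary cross-links (the nodes
clipped exactly onto the cube faces); interior cross-links equilibrate
freely. The network contribution to the macroscale Cauchy stress is the
boundary virial

    S_ij = (1/V) Σ_bc x_i r_j,    V = det F,

summed over boundary cross-links, with x the current node position and r
the reaction transmitted to the face (minus the sum of fiber forces acting
on the node — this sign makes a fiber in tension produce positive normal
stress). The matrix adds the compressible neo-Hookean stress from
W = G/2 (I₁ − 3 − 2 ln J) + K/2 (ln J)², with G = 4.2 kPa, ν = 0.47,
K = 2G(1+ν)/(3(1−2ν)) ≈ 68.6 kPa. Units project-wide: μm, μN, kPa; network
coordinates are dimensionless, and the unit-cube virial stress is read
directly on the kPa scale of the matrix (the calibration of A absorbs the
RVE size).

**Affine-boundary choice.** Affine (kinematic) RVE boundary conditions are
the simplest consistent homogenization closure; they are known to be
slightly stiffer than periodic conditions. The averaged-stress balance also
admits a surface term integrating the micro–macro stress fluctuation
against the boundary displacement gradient; the solver ships a coarse
per-node estimator of this term (equal area shares per boundary cross-link)
that is disabled by default and, when enabled, is added as a body-force
contribution and its magnitude logged. The default solver is therefore a
standard Galerkin scheme on the homogenized stress.

**Macroscale.** Trilinear hexahedra with 2×2×2 Gauss quadrature; every
Gauss point owns an independent network realization. Internal forces use
the total-Lagrangian form ∫ (∂N/∂X)ᵀ P dV₀ with P = J σ F⁻ᵀ, and the
consistent tangent is built per Gauss point by central finite differences
of P on the nine components of F (step 10⁻⁵), each perturbed evaluation
re-equilibrating the RVE warm-started from the converged interior
coordinates. Global Newton iterations stop when the free-dof residual
∞-norm falls below max(10⁻⁶ μN, 10⁻⁴ × reaction ∞-norm).

## Network generation and alignment

Isotropic RVEs are built by sampling uniform points on a margin-enlarged
cube, Delaunay-tessellating them, and clipping every edge to the unit cube,
which creates cross-links exactly on the faces. Alignment follows the
stretch-and-clip mechanism of the fiber-network homogenization literature:
node positions are stretched about the cube center by diag(s₁, s₂, s₃)
(connectivity kept, so directions tilt toward the stretched axes) and the
result is clipped back to the unit cube; the generator oversamples points
to compensate the clipped volume. Two refinements keep the exponential law
well-behaved: sampled points are thinned to a minimum pairwise separation,
and clip stubs shorter than 2% of the cube edge are dropped (they carry no
load at rest but let tiny interior motions produce enormous stretch
ratios). Interior components left unanchored by clipping are pruned.

The corpuscle policy stretches 3:3:1 along the two tangent axes of the
confocal ellipsoidal surface through the element centroid (the model's
abstraction of the concentric lamellae — no explicit layering); the skin
policy is transversely isotropic in the global skin plane, 3:3:1 about the
skin normal. The anisotropy magnitude is a config knob; 3:3:1 is the
package default. Within one element all eight Gauss points draw independent
networks (seeds derive reproducibly from (global seed, element, Gauss
index)); the frame is evaluated once per element at its centroid.

## RVE equilibrium solver

Interior cross-links minimize the network strain energy; the residual is
the interior nodal force vector and the Hessian the truss tangent
stiffness. The solver is damped Newton with (i) an energy line search
(Armijo) using a tabulated antiderivative of the fiber force — the
exponential law has no elementary strain-energy primitive, so Φ(λ) =
∫₁^λ (e^{B(s²−1)/2} − 1) ds is pretabulated on a dense grid — plus a plain
residual-decrease acceptance for the terminal Newton phase where the
tabulated energy flattens into interpolation noise; (ii) a trust cap on the
step ∞-norm (floppy compressed modes produce steps far outside the
quadratic model's validity); (iii) a Levenberg ridge when the Hessian turns
indefinite. If the iteration still stagnates at a fold (network
snap-through), the solve is retried by load continuation from the reference
configuration, and as a last resort with a small deterministic interior
kick. The interior force tolerance is 10⁻⁸·A ≈ 1.1×10⁻⁶ μN. Energy descent
makes convergence to a true equilibrium generic, but near folds the reached
branch can depend on the warm start; results are deterministic for fixed
inputs and solver settings.

## Geometry

The isolated PC is a half-ellipsoid (major axis 1 mm along y, minor axes
0.5 mm; flat base at z = 0) meshed by mapping a structured half-cube grid
through a smooth cube-to-ball map, so outer nodes sit exactly on the
ellipsoid; resolution n gives 4n³ elements. Embedded models place the full
ellipsoid in a rectangular skin block (epidermis 1.5×1.5×0.75 mm with the
center 0.375 mm deep; dermis 1.5×1.5×2.75 mm, 2.375 mm deep) on a graded
tensor grid with elements labeled by centroid and near-surface nodes
snapped radially onto the ellipsoid (the snap band is halved automatically
if an element would invert). The vertically oriented dermal PC cannot sit
at the horizontal model's depth (2.375 + 0.5 mm exceeds the 2.75 mm
domain); its center depth defaults to 2.125 mm, preserving the horizontal
model's 125 μm clearance to the base.

**Boundary conditions** (not fully constrained by the problem statement,
config-overridable): isolated PC — base on vertical rollers (u_z = 0) with
a pin at the base center and one in-plane rotational restraint; the base
must remain laterally free because the long-axis strain gauge pair lies on
it. Embedded models — base clamped, lateral faces free (roller walls are
available as an option, but confining the tall dermis column reverses the
sign of the horizontal corpuscle's long-axis strain, contradicting the
orientation sign behavior the model is meant to show).

**Indenter.** Indentation is a prescribed vertical (−z) displacement with
no contact search or friction. The cylindrical indenter is a rigid flat
punch: its plane starts at the highest footprint node and each surface
node within the 250 μm-diameter footprint (inclusive radius) is engaged
once the plane reaches it, displaced by the geometric overlap — on the
curved corpuscle dome this flattens the cap progressively, as a physical
contactor would. A `uniform` engagement option instead drags every
footprint node down by the full depth; on the dome that translates the
whole cap ("scooping") and floods the footprint rim with artificial shear
that masks the isotropic-vs-aligned stress contrast. On flat embedded
surfaces the two rules coincide; receptive-field sites indent a single
surface node.

## Experiments and metrics

* Long-axis strain ε = (l − l₀)/l₀ between the two interface nodes on the
  corpuscle's long axis (y; z for the vertical orientation) — the proxy for
  neurite stretch.
* Von Mises stress per element: √(3/2 s:s) of the deviator, averaged over
  the 8 Gauss points. Von Mises strain uses the equivalent-strain
  convention √(2/3 e:e) on the Green–Lagrange strain (reported in
  millistrain where maps are drawn).
* Cross-section area strain: shoelace area of the ordered y = 0 boundary
  node loop of the PC in the x–z plane, deformed vs reference.
* Receptive fields: one independent single-node 10 μm indentation per
  surface site; the default site grid is the x ≥ 0, y ≥ 0 quarter of the
  surface nodes (mirrored for presentation), exploiting the model's mirror
  symmetry. The spatial-sensitivity summary is the coefficient of variation
  of |ε| across sites; the zero-strain contour is linearly interpolated
  along grid rows.

## Problem sizes and what the tests show

Full-scale runs (500–700 fibers per RVE, meshes of a few thousand
elements) reproduce the study conditions; the package defaults to them in
`RunConfig`. The acceptance script (`scripts/acceptance.py`) uses the
desk-scale study conditions: a 256-element isolated mesh, a coarse graded
dermis mesh, ~150-fiber RVEs, three network seeds, 5 μm increments to
25 μm. The pytest suite runs smaller still (32–108-element meshes, 40–140
fiber RVEs) so the whole suite stays in minutes; those sizes check the
mechanics, ordering properties and determinism, not mesh-converged values.
The synthetic geometry/network generators emulate the stated study system
(geometry, material constants, network sizes, protocols); they do not
emulate biological variability, receptor-to-receptor geometry differences,
explicit lamellae, interlamellar fluid, or any dynamic/viscoelastic
response, so passing tests speak to the static, instantaneous model only.

Observed desk-scale behavior worth recording: with rigid-punch engagement
the isotropic model's peak Von Mises stress next to the indenter is about
twice the aligned model's (the uniform-depth rule buries this contrast
under footprint-rim shear). The isotropic-to-aligned long-axis strain
ratio at 25 μm sits around 3–4 at desk scale; it is insensitive to mesh
refinement (n = 3, 4, 5) and to the engagement rule, rises when RVEs grow
to full scale (500–700 fibers soften the aligned strain by ~30%), and
moves with the anisotropy magnitude — which this package leaves at its
3:3:1 default rather than calibrating to outcomes. The end-to-end
long-axis gauge also averages the shielded core with the far field, which
dilutes core-shielding contrast at coarse resolution. The cross-section
area strain is dominated by the dent of the indenter itself (≈ −3…−5% at
25 μm for either policy), so its ratio to the long-axis strain is an
order of magnitude above the axis strain's own contrast.

## Numerical choices and degenerate inputs

Delaunay degeneracies are retried with a 10⁻⁹ jitter and a logged warning.
Fiber-force exponents are clamped at B·E_f = 60 inside the solver (line
search rejects such states; a clamp active at convergence reports fiber
overflow). Element Jacobians are validated at all Gauss points; meshes
reject duplicate nodes and non-conforming faces. A centroid exactly at the
ellipsoid center has no defined surface normal and falls back to the global
frame with a log message. File writers use fixed float formatting and
sorted keys so identical inputs give byte-identical outputs.

## Known limitations

Static equilibrium only — no vibratory response, interlamellar fluid flow,
viscoelasticity, or receptor electrophysiology. Affine RVE boundaries
overestimate network stiffness relative to periodic closures. The
prescribed-footprint indenter ignores contact lift-off, which exaggerates
the indented volume on the curved corpuscle surface. Desk-scale meshes
resolve the embedded corpuscle with few elements across the minor axis;
receptive-field maps at that scale are indicative, not converged.
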