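# Methods

## Scope and intent

`tonguefem` implements the biomechanical core of a muscle-driven tongue
simulator: nearly incompressible hyperelastic soft tissue discretized with
quadratic tetrahedra, active muscle elements, and the supporting
methodology (mesh convergence, muscle partitioning, phoneme presets).  It
deliberately does **not** implement subject-specific geometry
reconstruction: all end-to-end behaviour is demonstrated and tested on a
parametric tongue phantom.

## Constitutive model

**Passive tissue.**  Two-term Yeoh strain energy with a quadratic
volumetric penalty:

    W = C10 (Ī₁ − 3) + C20 (Ī₁ − 3)² + K/2 (J − 1)²,
    Ī₁ = J^(−2/3) tr(C),  J = det F,  K = 2 C10 / (1 − 2ν).

Defaults: C10 = 192 Pa, C20 = 90 Pa, ν = 0.49 → K = 19 200 Pa.  Tissue
density defaults to 1040 kg/m³ (standard soft-tissue value; the model it
follows states densities only for auxiliary structures).  The passive
response is isotropic — experimental reports disagree on the direction of
maximal passive muscle stiffness, so anisotropy is restricted to the active
term.  Stress and tangent are derived analytically in the reference
configuration (S = 2 ∂W/∂C, ℂ = 4 ∂²W/∂C²) and verified against central
finite differences of the energy in the test suite (1e-5 relative).

**Active muscle.**  Each muscle is a set of elements with a unit reference
fiber direction per element.  Activation adds a uniaxial Cauchy stress
σ_max·a·f_l(λ)·f_v(ε̇) along the deformed fiber (tension-positive: a
positive activation contracts the fiber once equilibrated).  The precise
force-length/velocity curves of the source formulation are not published,
so declared substitutes are used:

- f_l(λ) = exp(−((λ − λ_opt)/w)²), λ_opt = 1.0, w = 0.35;
- f_v: Hill hyperbola (1 + ε̇/ε̇_max)/(1 − ε̇/(k_v ε̇_max)) for shortening
  (zero below −ε̇_max), linear enhancement capped at 1.4 for lengthening;
  ε̇_max = 5 s⁻¹, k_v = 0.25.

All four parameters are configurable per muscle.  Activation schedules
prescribe a fiber stress s(t) (Pa, piecewise linear); a = s(t)/σ_max with
σ_max defaulting to 1.2× the largest preset stress for that muscle (so
a ≤ 0.84), with a 10 kPa floor for muscles never activated in the presets.
Schedule stresses are interpreted as Cauchy fiber-stress magnitudes.
Elements shared by two muscles (the declared Verticalis/Transversalis
interdigitation) superimpose two single-fiber contributions.

In transient runs the force-velocity factor uses the fiber strain rate of
the previous step (semi-implicit), passed through a first-order low-pass
filter (time constant 0.15 s by default): without the filter the one-step
lag in f_v can sustain a numerical limit cycle when per-step strain rates
approach the maximal shortening rate.  In statics f_v = 1.

## Discretization and solvers

Total-Lagrangian TET10 elements, 4-point quadrature for stiffness (exact
for affine elements), exact barycentric-monomial integration for the
consistent mass, a degree-5 collapsed Gauss rule for spatial body-force
fields.  Meshes are straight-edged (midside nodes at edge midpoints);
element inversion (det F ≤ 0 at any quadrature point) aborts the step.

Statics: Newton-Raphson with backtracking line search (strict residual
decrease, α down to 1/256), a 20 mm trust-radius cap on increments, LU
reuse while the residual contracts by ≥2× per iteration, and load
continuation that ramps gravity, imposed displacements and activations
together, halving on failure (max 8 cuts) and occasionally attempting a
double step to leap fold points in the equilibrium path.  Convergence:
‖r‖ ≤ 1e-6 × max(‖f_ext‖, ‖r₀‖).

Transients: Newmark-β (β = 1/4, γ = 1/2) or a dissipative backward-Euler
variant, consistent mass, Rayleigh damping C = αM + βK₀ (defaults
α = 20 s⁻¹, β = 0.002 s; K₀ is the rest tangent).  These damping values
are package defaults — the source model's damping and activation timing
are unpublished.  A steady-state detector flags the first sample after the
last schedule breakpoint whose kinetic energy falls below a fraction
(default 1e-5) of the running maximum.

Strongly activated postures (preset stresses ≥ 20 kPa) use *dynamic
relaxation*: a short damped transient through the activation ramp followed
by a warm-started static polish to the 1e-6 residual.  Static continuation
paths for such loads frequently encounter limit points; the damped
transient walks through them.

Linear systems use sparse LU (COLAMD).  Nested refinement hierarchies can
use a two-grid preconditioned conjugate-gradient solver (symmetric
multiplicative cycle: damped Jacobi, Galerkin coarse correction through
the red-refinement prolongation, damped Jacobi), which keeps fine-level
convergence runs within a single-CPU budget.  The Jacobi weight is
auto-scaled from a power-iteration estimate of λ_max(D⁻¹K) — a fixed
weight can exceed the smoother's stability bound at strongly deformed
states and render the preconditioner indefinite.

Mid-sagittally symmetric problems can be solved on the symmetric half
phantom with the u_z = 0 plane condition; a test verifies half/full
agreement implicitly through the symmetry criterion on the full model.

**Contact and attachments.**  Rigid triangulated obstacles act through a
frictionless node-to-triangle penalty (normals oriented toward the
deformable body); doubling the penalty halves the converged penetration,
which the tests verify.  1D cable muscles of the hyoid suspension are
simplified to linear springs from node sets to fixed anchor points.  Bones
are not meshed: the palate may act as a rigid contact surface, and the
mandible/hyoid act through fixed or displacement-driven attachment node
sets.

## The phantom (what the generator emulates, and what it does not)

The phantom is a smooth map of a box onto a tongue-like solid (75 × 50 ×
40 mm by default): flat inferior face, convex dorsum with an anterior
taper, exact mirror symmetry in Z (built on a half grid and reflected, so
symmetric loads yield numerically symmetric solutions).  Kuhn (6-tet)
cells are promoted to TET10.  Muscle element sets are centroid-rule
regions: a mid-sagittal Genioglossus fan radiating from a genial-tubercle
analog at mandible level (GGh below the quasi-horizontal tendon plane at
0.28 H; GGp/GGm/GGa angular sectors at 55°/100° boundaries — free
parameters, since the source partitioning was tuned on imaging data and
never published as coordinates), lateral-dorsal Styloglossus bands,
posterior-lateral Hyoglossus sheets anchored toward hyoid corner points,
floor layers for Geniohyoid (central, longitudinal) and Mylohyoid (lateral
sling), a sub-dorsal Superior Longitudinalis layer, an inferior-lateral
Inferior Longitudinalis band, and an interdigitating
Verticalis/Transversalis core (the one sanctioned two-muscle overlap).

Two fiber-field choices matter for the directional muscle behaviour.  The
anterior Genioglossus fibers blend the radial fan chord strongly toward
vertical (they insert near-vertically into the blade and tip from below),
which makes GGa activation lower the tip instead of dragging the whole
anterior body backward.  The in-body Styloglossus fibers are predominantly
longitudinal (vertical component damped to 0.35): the muscle courses along
the lateral dorsum, and only its external branches turn up toward the
styloid process.  Those external branches are represented by
activation-scaled cable springs ("contractile cables", the same
simplification the source model applies to its hyoid muscles) from
posterior-superior-lateral insertion node patches to virtual styloid
anchor points; their tension is the SG activation times a linear spring
force (default 0.002 N/mm per node).  With this arrangement SG activation
elevates the velar dorsum (front-back bunching plus external hoisting) and
retracts the apex.

What a green test on the phantom establishes: the solvers, the active
element, the partitioning logic and the convergence methodology behave
correctly on a tongue-like geometry.  What it does not establish: anatomical
fidelity, subject-specific tongue shapes, or quantitative agreement with
imaging data — the phantom has idealized muscle paths and no palate/teeth
geometry.

Default sizes and loads are the stated conditions of the problem domain:
gravity 9.81 m/s² (upright, −Y), the five phoneme presets with their
published activation plateaus (up to 90 kPa) and jaw/hyoid displacements,
and the 1 mm convergence threshold (EMA accuracy).  The default phantom
resolution (7.5 mm, ≈3000 TET10 nodes) is the desk-scale compromise: fine
enough to host all 12 muscle groups, small enough for minutes-scale runs.

## Convergence methodology

A coarse phantom is uniformly red-refined (1→8; parent nodes keep their
indices, so landmark nodes are shared across levels; octahedron diagonals
are chosen shortest-first, a mirror-symmetric rule).  Node sets extend to
new midside nodes whose edge endpoints both belong to the set, keeping
region constraints consistent across levels.  The same static gravity load
(floor and bone attachments fixed) is solved on every level, warm-starting
each level from the prolonged coarser solution; per-landmark absolute
errors (Euclidean distance of displacement vectors, mm) are reported
against the finest level, and the coarsest level with all errors below the
threshold is selected.  A separate manufactured-solution study (a
divergence-free trigonometric displacement with its exact linear-elastic
body force on a cube) measures the H1-seminorm convergence rate; quadratic
tetrahedra give ≈2.

Desk scale: the default series spans ~10² to ~3 × 10⁴ nodes.  The published
reference analysis used meshes up to 3.4 M nodes; those node counts (and
the associated error table) are outside desk scale and are not reproduced.

## Known limitations

- **Quasi-incompressibility under the published activation stresses.**
  The penalty bulk modulus implied by the published formula
  (K = 2·C10/(1−2ν) = 19.2 kPa for C10 = 192 Pa) is *small* relative to
  the published activation plateaus (2–90 kPa).  A uniaxial active stress
  s adds s/3 to the mean stress of an activated element, so its volume
  ratio settles near J ≈ 1 − s_eff/(3K), where s_eff = s·f_l(λ) is the
  force-length-limited effective stress.  For the /i/ preset (GGh 10 kPa)
  this predicts J ≈ 0.88 in the horizontal Genioglossus, and the simulated
  phoneme postures show elementwise J down to ≈0.8 (moderate presets) and
  ≈0.5 (large ones) — outside a ±7% quasi-incompressibility band.  This is
  a property of the stated parameter set (uniaxial active stress + low
  penalty modulus), not a discretization artifact; enforcing J ≈ 1 under
  these stresses would require either a much larger bulk modulus, a mixed
  u/p formulation with a hard constraint, or a deviatoric projection of
  the active stress, all of which would depart from the stated model.  The
  corresponding acceptance test is left failing with this analysis.
- Static continuation near large activations encounters genuine limit
  points; dynamic relaxation is the robust route, at transient cost.
- The Hill curve shapes, damping, and activation timing are declared
  substitutes for unpublished source values.
- Contact is frictionless, node-to-rigid-triangle only; no self-contact.
- The phantom's muscle geometry is parametric; directional muscle-effect
  tests check displacement *signs*, not magnitudes.
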