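# Methods

`duramech` implements the inverse-mechanics workflow of a bulge inflation
test on a thin soft-tissue membrane (the motivating tissue is cerebral
dura-arachnoid membrane): a circular specimen clamped over a pressurized
chamber, its surface motion measured by two calibrated cameras, from which
local strain, local Cauchy stress, rupture stress and global hyperelastic
parameters are recovered. This note records the models, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Constitutive models

The membrane is treated as isotropic, incompressible and hyperelastic.
Two strain-energy densities are used (principal stretches λ1, λ2,
λ3 = 1/(λ1λ2)):

- Ogden (one term): ψ = μ/α (λ1^α + λ2^α + λ3^α − 3), parameters μ (Pa) and
  α (–). Initial shear modulus μ_s = μα/2; Young's modulus E = 3 μ_s for an
  isotropic incompressible solid.
- NeoHookean: ψ = C1 (λ1² + λ2² + λ3² − 3) with C1 = μ_s/2. It is the α = 2
  special case of the Ogden form with C1 = μ/2, a relationship used as an
  algebraic cross-check in the tests.

In uniaxial tension (λ1 = λ, λ2 = λ3 = λ^(−1/2)) the engineering (first
Piola-Kirchhoff) stress is P = μ(λ^(α−1) − λ^(−α/2−1)) and the Cauchy stress
is σ = λP. Curve fitting targets engineering stress by default — that is the
measure a load cell and the initial cross-section produce — with Cauchy
stress available behind a flag; which measure the emulated experiments
fitted is not decidable from their description, so the choice is explicit
and switchable.

## Surface measurement

Feature *detection* in images is out of scope; the pipeline consumes sparse
feature trajectories (pixel coordinates per track, frame and camera) plus
calibrated pinhole cameras.

- **Triangulation.** Each correspondence is triangulated by the linear DLT
  followed by one Gauss-Newton step on the four reprojection residuals.
  Ray pairs subtending less than 0.1° are rejected as degenerate.
- **Track filtering.** Only tracks valid in every frame are kept (tracks die
  when the speckle washes out). Gross outliers are then removed by a robust
  rule: a track is dropped when its mean pixel speed differs from the
  population median by more than `k_mad` (default 5) median absolute
  deviations. The rule is deliberately parameter-light; the threshold is
  config-exposed because the underlying experimental practice is described
  only qualitatively.
- **LOWESS.** All scattered-data interpolation (reference surface height
  field, per-frame displacement fields) uses locally weighted quadratic
  regression with tricube distance weights over the `span` fraction of
  nearest samples and 4 iterations of bisquare robustness reweighting,
  applied componentwise to vector fields. A quadratic local basis
  reproduces degree-≤2 fields exactly; its leading error on a curved surface
  is the cubic remainder over the local window, so the appropriate `span`
  shrinks as sampling density grows. The default span is 0.15 (suitable for
  a few hundred scattered samples); the synthetic sphere studies with ~10³
  tracks use 0.08. Both are configuration, not calibration: the choice is
  made from the window-size argument above, not from test outcomes.
- **Analysis mesh.** The reference mesh is built on the best-fit (PCA) plane
  of the triangulated cloud: a triangular (hex) lattice of node spacing `h`
  clipped to a circular region of interest, plus a ring of nodes exactly on
  the rim, Delaunay-triangulated in-plane. A plain square grid clipped to a
  circle leaves sliver triangles at the rim that visibly poison the inverse
  equilibrium system; the lattice keeps element quality uniform. Node
  heights and per-frame nodal displacements come from the LOWESS
  interpolant; default spacing is 1/10 of the ROI radius.

## Membrane kinematics

Each triangular element carries an orthonormal in-plane reference frame
{U, V}, U being the in-plane projection of a chosen global direction. The
element's affine map follows from its three nodal position pairs. The
reference frame is carried into the deformed element plane by the minimal
rotation aligning the undeformed and deformed element normals, and the 2×2
in-plane deformation gradient F collects the components of the advected
frame vectors in that carried basis. Writing F directly as dot products of
the advected vectors with the *reference* basis is equivalent while the
element stays in its reference plane, but is not objective under
out-of-plane rigid rotation; the corotational form is, and it reproduces any
homogeneous in-plane map to machine precision (property-tested over random
affine maps composed with 3D rotations).

From F: logarithmic strain E = ½ log(FᵀF) via eigendecomposition of the
right Cauchy-Green tensor; principal stretches λ1 ≥ λ2 as the square roots
of its eigenvalues; incompressible thickness h = h0/det F. The identity
tr E = ln(λ1λ2) = −ln(h/h0) holds by construction and is asserted in tests.

## Inverse membrane stress

Under the pure membrane assumption (no bending, σ33 = 0) the in-plane
Cauchy stress field balances the pressure through the deformed geometry.
Unknowns are the three in-plane components (σ_uu, σ_vv, σ_uv) at each node,
expressed in nodal tangent bases built from area-weighted adjacent-facet
normals. Equations:

- three force-balance rows per element:
  p·A_e·n_e + Σ_edges h_edge·L·(σ_edge·m_edge) = 0, with σ_edge the mean of
  the two end-node stress tensors, m_edge the outward in-plane edge normal,
  and the whole row divided by the element thickness;
- per boundary node, the clamped-edge traction is required to have no
  component along the edge (no shear) and none along the surface normal
  (no moment). The second condition is satisfied identically by the
  in-plane parameterization; its row is assembled anyway so the equation
  count matches the stated structure.

Two details go beyond the one-paragraph description this scheme condenses:
the traction across a shared edge is evaluated in the plane of the *averaged*
adjacent facet normals with edge-averaged thickness, so the two elements
exchange equal and opposite forces (action–reaction; with per-facet planes
the imbalance acts as a spurious load), and the per-element thickness
normalization makes the solution exactly homogeneous of degree −1 under a
uniform thickness change, an invariant the tests assert exactly.

The overdetermined sparse system is solved in the least-squares sense after
column scaling (dense QR up to 6000 unknowns, LSMR beyond); no
regularization is applied by default (a ridge term is config-exposed).
Element tensors are the arithmetic mean of the three nodal tensors rotated
into the element basis; principal stresses follow by eigendecomposition.

Accuracy on the analytic sphere (below): interior principal stresses within
~3% of the Laplace value p·r/(2h) at ~340 nodes, errors decaying roughly
first order in mesh size (flat-facet geometry error dominates). Two honest
caveats: (i) the *max* error over an interior defined by a fixed number of
edge rings does not halve under refinement, because the rim boundary layer
moves closer in physical distance — convergence is measured as the median
error over a fixed apex region; (ii) the per-element principal-stress
*ratio* σ1/σ2 of a near-equibiaxial field is biased above 1 by the
deviatoric discretization error (eigenvalue splitting is one-sided), so it
sits within [1.00, ~1.04] in the interior rather than exactly 1, while the
stretch ratio λ1/λ2 is exactly 1 on the synthetic cap.

**Rupture stress** is the area-weighted mean of the element first-principal
Cauchy stress over a user-supplied damaged-element mask, evaluated at the
frame *before* the first visibly damaged frame. Masks touching the clamped
rim trigger a warning (such cases are excluded in practice).

## Total-energy identification

Fitting a constitutive law element-by-element would be noisy and leaves the
averaging question open, so identification is global. The experimental
strain-energy density per element accumulates σ : ΔE over frames by the
trapezoidal rule (the off-diagonal term counts twice; the thickness
direction contributes nothing since σ33 = 0), and the total
W_exp = Σ_e w_e V_e uses constant reference volumes V_e = A0_e·h0_e
(incompressibility). For incompressible response the Cauchy-stress /
log-strain work density equals energy per reference volume, which is what
makes W_exp directly comparable with the model energy
W_model = Σ_e V_e ψ(λ1e, λ2e). On the 50-frame default loading schedule the
trapezoidal accumulation agrees with the closed-form energy to 0.05% at full
load; only the first one or two near-zero-energy increments exceed 1%
relative error.

Parameters minimize Σ_i (W_exp^i − W_model^i)² over frames, via trust-region
nonlinear least squares; μ (or C1) enters linearly and is profiled out of
the starting values, and the Ogden fit is multistarted over
α ∈ {2, 5, 10, 20}. R² is 1 − SSR/SST about the mean of W_exp.

**Confidence intervals.** The 95% half-widths come from the HC3
(leverage-corrected sandwich) asymptotic covariance at the optimum rather
than the classic s²(JᵀJ)⁻¹ formula. Energy noise is effectively
multiplicative — the residual scale grows with the energy, and the late,
high-energy frames carry nearly all the leverage — so the homoscedastic
formula materially understates the parameter variance (Monte-Carlo coverage
~80% instead of 95% under 2% multiplicative noise), while HC3 stays
calibrated (~94–96% in the same experiment, which the tests assert).

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions of the emulated
experiments: clamp radius 15 mm, initial thickness 375 μm, Ogden μ = 234 kPa
and α = 8.19, a ~2.9 kPa/s pressure ramp sampled at one frame per second
(50 frames), and a final stretch (1.65) at which the chamber pressure
reaches the ~164 kPa burst level. The uniaxial generator produces Ogden
curves with μ = 450 kPa, α = 16.55, 100 points to λ = 1.22 (22% failure
strain) and 2% multiplicative noise.

The inflation forward model is a *uniformly stretched spherical cap*: the
reference geometry is a cap of a sphere of the clamp radius, inflation is
pure radial scaling, the equibiaxial Cauchy stress is
σ = μ(λ^α − λ^(−2α)), thickness thins as h0/λ², and pressure follows the
Laplace balance p = 2hσ/(λ r0). This gives exact closed-form ground truth
for every element and frame (the decisive property for testing an inverse
method), at the price of physical fidelity at the rim: a real clamped
membrane is flat at zero pressure, inflates inhomogeneously, and satisfies
a boundary-value problem this model does not solve. Oracle comparisons
therefore restrict to elements at least two edge-hops from the rim. Virtual
stereo tracks add, per a seeded noise model: Gaussian pixel noise, dropout
(a track truncated at a random frame, emulating speckle washout by leaking
water), and gross outliers (a constant 20·σ_px pixel offset applied from a
random frame onward — a jump, so the mean-velocity filter can see it).

Consequences for interpretation: passing tests demonstrate the correctness
of the kinematics, the equilibrium solver, the energy bookkeeping and the
optimizer on equilibrium-consistent, materially homogeneous, isotropic
data. They do not probe clamped-edge boundary layers, material or thickness
heterogeneity, anisotropy, viscoelasticity (explicitly out of scope), DIC
decorrelation, or camera miscalibration.

## Problem sizes and numerical defaults

The default synthetic mesh targets ~300 nodes (an icosphere subdivision
clipped to the cap), where one inverse-stress solve takes well under a
second and the full 50-frame chain runs in about half a minute; the
refinement study uses ~1300 nodes. These sizes were chosen so that the
discretization error of the stress solver (the pipeline's accuracy
bottleneck, ~2–3% interior) is comfortably inside the 5% oracle bands while
the whole validation suite stays quick to run. Fitting tolerances are tight
(`xtol = ftol = gtol = 1e-14`) because the objectives are tiny
least-squares problems; α is bounded to [0.05, 100]; ties in the multistart
are broken by lowest cost.

## Known limitations

- The element force balance is first-order accurate in mesh size on curved
  geometry; principal-stress fields inherit a percent-level wobble at
  practical resolutions.
- The equilibrium system is ill-conditioned (condition ~10⁷ after column
  scaling): near-null "floppy" stress modes exist, concentrated at the rim;
  rim-adjacent stresses should not be trusted, which is also why rupture
  masks touching the rim warn.
- Energy identification assumes a single homogeneous parameter set; it
  deliberately does not produce parameter maps.
- The work-conjugacy identification (Cauchy stress against logarithmic
  strain as energy per reference volume) is exact only for isochoric
  deformation; the incompressibility assumption is load-bearing.
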