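# Methods

## The model

Retinal vessels live on a (nearly) spherical surface, but fundus cameras
record flat images.  `so3track` tracks curvilinear structures directly in
spherical coordinates by minimizing, over sphere curves `n(s)` with fixed
endpoints *and* end directions,

    L[n] = ∫ C(n(s)) · sqrt(ξ² + k_g²(s)) ds,

where `s` is spherical arclength, `k_g` the geodesic curvature (curvature
relative to great circles), `ξ > 0` a stiffness weighting length against
bending, and `C ≥ δ > 0` an external cost derived from the image (low on
vessels).  The functional is the spherical analog of the classical
elastica-type contour models in the plane; its minimizers follow vessels
while penalizing sharp bends.

The problem is lifted to the rotation group SO(3): a sphere point plus a
direction is a rotation, charted here as
`R(x, y, θ) = exp(y A3) exp(−x A2) exp(θ A1)` with latitude `x`,
longitude `y` and orientation `θ`.  Motion is restricted to the rank-2
distribution spanned by the left-invariant fields `X1` (spatial: move
along the current direction on the sphere) and `X2 = ∂θ` (turn in
place), with metric `C²(ξ² u1² + u2²)`; this is a sub-Riemannian (SR)
structure, a spherical Reeds–Shepp car.  Curves through the lift whose
spatial control `u1` stays positive project to minimizers of `L`.

## Exact geodesics (uniform cost)

For `C = 1` the Pontryagin maximum principle gives left-invariant momenta
`(h1, h2, h3)` with conserved Hamiltonian `2H = h1²/ξ² + h2² = 1` and
Casimir `M² = h1² + h2² + h3²`.  Implementation routes:

* **Vertical dynamics in SR arclength `t`.**  In half-angle variables
  (`h1 = ξ cos β/2, h2 = sin β/2, c = 2h3/ξ`) the momenta follow a
  mathematical pendulum `β̈ = −r sin β`, `r = 1/ξ² − 1`.  All regimes —
  oscillation, rotation, separatrix, the linear case `ξ = 1`, and `ξ > 1`
  via the symmetry `β → β + π, r → −r` — are evaluated in closed form
  with Jacobi elliptic functions (`scipy.special.ellipj`).
* **Horizontal dynamics by momentum-frame reconstruction.**  The spatial
  momentum vector `m = R(t) p(t)` with `p = (h2, −h1, h3)` is a constant
  of motion.  Writing `R = E(0) Z(α) E(t)ᵀ`, with `E` an explicit
  orthonormal frame built from `p` (section vector `e2`; nondegenerate
  away from pure great circles, which are handled in closed form), the
  whole rotation reduces to one scalar quadrature

      α'(t) = 1/M − J·h1²(t) / (ξ² M (M² − h1²(t))),

  where `J = h3² − (ξ²−1) h2²` is another invariant.  Chart angles are
  read off the reconstructed matrix with principal-branch `arg`.
* **Spherical-arclength (`s`) parameterization.**  Before the first cusp
  the vertical system is linear: `h2(s), h3(s)` are elementary in
  `χ = sqrt(ξ²−1)` (principal complex root for `ξ < 1`) and
  `h1 = ξ sqrt(1−h2²)`.  The same reconstruction applies with
  `α'(s) = ξ²/(h1 M) − J·h1/(M(M²−h1²))`.  In the elliptic oscillatory
  regime (`ξ < M < 1`) the quadrature has the closed form
  `α = M/(ξ sqrt(1−ξ²)) [ΔF − ΔΠ]` in incomplete elliptic integrals of
  the first and third kind (Carlson forms with quasi-period reduction);
  it is used as a fast path and cross-checked against adaptive quadrature
  in the tests.
* **Cusps.**  A cusp is a sign change of `u1 = h1/ξ²`; the first cusp
  arclength `s_max` is the minimal positive root of `h1(s) = 0`, obtained
  by solving the quadratic in `z = exp(s χ)` through the complex
  logarithm (with the real period `2π/|χ|` for `ξ < 1`), verified against
  the vertical solution and guarded by a bisection fallback.

Every closed form is tested against independent adaptive ODE integration
of the Hamiltonian system (`DOP853`, tolerances 1e−12); agreement is at
the 1e−9 level over `t ∈ [0, 3]` across all three regimes.

## Distance maps: anisotropic fast marching

The SR distance `W` from the seed solves the eikonal equation
`sqrt((X1 W)²/ξ² + (X2 W)²) = C` in the viscosity sense.  Numerically the
SR metric is approximated by a Riemannian one that penalizes the
forbidden direction `X3` by `ξ²/ε²` (default `ε = 0.1`), assembled in the
fixed chart basis as `M_ε = Ωᵀ diag(C²ξ², C², C²ξ²/ε²) Ω` with `Ω` the
left-invariant coframe.

Discretization: a monotone semi-Lagrangian (Tsitsiklis-type) update on
the 26-neighbor cube, triangulated into 48 tetrahedra covering every
direction; the per-simplex minimization has a closed form (a scalar
quadratic, with edge/vertex fallbacks).  Because strong anisotropy breaks
strict heap causality on a compact stencil, the causal fast-marching pass
is followed by FIFO label-correcting relaxation (processed in ascending-W
order) to the fixed point of the discrete operator; a pure Gauss–Seidel
sweeping solver over the same operator is available as an independent
scheme and the two are cross-checked in the tests.  The solver is
deterministic: identical inputs give identical maps.

Numerical choices that matter:

* **Grid.**  `x ∈ [−x_cap, x_cap]` (default 1.4, up to 1.5 for
  whole-chart experiments; the chart is singular at `|x| = π/2`), `y, θ`
  periodic on a `k·h` lattice so the identity is a node.  Default
  working resolution 51×101×101 (about 25 s per solve on one core);
  results at this resolution are first-order accurate, with probe errors
  around one grid spacing and observed error ratios ≈ 0.42–0.65 under 2×
  refinement.  The reference resolution 201×401×401 is configured via a
  preset but takes tens of minutes.
* **Seed initialization.**  The discrete scheme is least accurate where
  characteristics bend near the source.  For uniform cost the metric is
  left-invariant, so a ball of SR radius ~0.5 around the seed is
  initialized exactly by dense sampling of the group exponential map
  (vectorized RK4 over ~41k momenta; earliest nearest-node arrival).
  This reduced endpoint errors by roughly 3× in our verification runs.
  For data-driven costs the initialization falls back to a one-cell
  shell with the local metric norm.
* **Fixed-point tolerance** 1e−4 in `W` units — well below the O(h)
  scheme error, above float noise.

## Backtracking and curvature read-out

The optimal curve to an endpoint solves
`γ' = −(u1 X1 + u2 X2)` with controls read from the map,
`u1 = X1(W)/(ξ²C²)`, `u2 = X2(W)/C²`.  `W` is interpolated with
tri-cubic splines (periodic in `y, θ`; the non-periodic `x` axis is
edge-padded) and differentiated by central differences of the
interpolant.  The descent direction additionally carries the
`(ε²/ξ²) X3(W)` component of the inverse Riemannian metric — it vanishes
in the SR limit but re-centers the discrete path inside narrow cost
valleys.  Integration is classical RK4 with unit chart speed and step
half the smallest grid spacing (stable for any cost magnitude); the walk
stops within 2.5 cells of the seed, appends it, and reports the path in
normalized time `τ = W/W(endpoint)`.

The geodesic curvature of the spherical projection is read directly from
the map, `κ_g = ξ² X2(W)/X1(W)`; samples with
`|X1(W)| < 0.05·‖(X1W, X2W)‖` are flagged cusp-suspect instead of
reported (a sign change of the spatial control is a cusp; a threshold is
required in the discrete setting).  An independent Gauss–Bonnet
finite-difference estimate `k_g = n″·(n × n′)` of any unit-speed sphere
curve, and planar curvature of the camera projection, provide the
comparison read-outs.  Gradients of a first-order `W` are noisy at the
few-percent level; curvature profiles are median-filtered over 5 samples
before comparison, and read-outs within SR distance ~0.25 of the seed
(where `W` is not differentiable) are excluded.

## Camera model

The reduced schematic eye: eyeball radius 1, nodal point at distance
`a = 13/21` from the center, camera plane at `c = 4/5` behind the
sphere, magnification `η`.  The central projection `(x, y) → (X, Y)` and
its closed-form inverse are implemented as printed above; `η ≠ 1` is
handled by rescaling inputs (congruency + scaling).  The visual axis is
assumed to coincide with the optical axis.  Derived quantities: maximal
imaged angle (`≈ 0.63` rad at fundus half-angle π/8), area distortion
`J(x, y)` (0.77 center → 1.11 edge), and global length distortion
(`≈ 7%` at the field edge).  `c` is a configurable default; the removable
singularity of the global distortion at `y = 0` is filled with its
analytic limit.

## Vesselness and cost

Dark tubes on a bright background are detected by the standard
multiscale Hessian vesselness: Gaussian-derivative Hessians at scales
`s = σ²/2 ∈ {2,3,4,5}` pixels (truncation 4σ, reflective boundary; the
image mean is removed first so the truncated kernels are exactly
offset-invariant), eigenvalues ordered by magnitude, per-scale response
`exp(−λ1²/2β²λ2²)(1 − exp(−(λ1²+λ2²)/2c²)) U(λ2)` with `β = c = 0.3`,
maximized over scales; `λ2 = 0` maps to 0, and the unit step selects
intensity valleys (dark vessels).  No scale normalization is applied, so
the raw response magnitude depends on image contrast.

The cost on the sphere is `G = (1 + VF(Π(x,y)) / (λ‖VF‖²∞))⁻¹`, sampled
bilinearly through the camera projection, replicated along θ (the cost
depends on spherical position only), floored at `δ = 1e−3`, and equal to
1 outside the camera footprint.  The squared sup-norm is implemented as
printed; because it makes the effective strength depend on the raw
response magnitude, a `normalize_vesselness` switch (default off)
divides `VF` by `‖VF‖∞` first so that `λ` acts on a [0, 1] response.
Note the direction of `λ` under this formula: small `λ` strengthens the
cost (data-dominant tracking), large `λ` flattens it toward uniform
(geometry-dominant).

Tracking between arbitrary oriented points re-centers the problem at the
identity: the cost field is resampled under the left action taking the
seed to `e` (the boundary condition is fixed there), and the backtracked
path is mapped back through the same rotation.

## Synthetic data

The phantom generator renders parametric centerlines confined to the
retinal field of view (`|x|, |y| ≤ 0.63`) as tubes with Gaussian angular
cross-section (half-width parameter = Gaussian σ) of contrast 0.7 on a
unit background, supersampled 4× relative to the pixel pitch, projected
to a flat 256² camera raster through the schematic eye, plus seeded
additive Gaussian noise (σ = 0.02).  All randomness flows through one
seeded generator; equal seeds give bit-identical phantoms.

What it emulates: the geometry of fundus photography (spherical object,
central projection, dark vessels, additive noise) at tube widths the
default tracking grids can resolve (angular σ = 0.05 ≈ one chart cell at
51×101×101; thinner tubes alias on the chart grid and are outside the
default study conditions).  What it does not emulate: illumination
gradients, the optic disc, vessel caliber variation, branching, and
camera blur — so passing tests demonstrate correctness of the geometry
and of the pipeline coupling, not segmentation-grade robustness on
clinical images.

End-to-end study conditions used in the verification suite: S-shaped
tube (amplitude 0.15, half-span 0.45), stiffness ξ = 1.5, normalized
vesselness with λ = 0.2 (cost-dominant but not extreme: cost contrast
~1:10; at contrasts beyond ~1:30 the discrete valley becomes too stiff
for reliable backtracking — a known limitation), scales {4, 6, 9, 12}
matched to the projected tube width.

## Known limitations

* Optimality past cut/Maxwell points is an open problem; the solver
  returns the globally optimal (FM) geodesic but no conjugate-point
  check is performed along backtracked paths, and stalls near the cut
  locus raise errors rather than being resolved.
* The cuspless-only variant of backtracking (clamping the spatial
  control nonnegative) is exposed but experimental.
* First-order accuracy of the eikonal scheme: endpoint distances carry
  ~1-cell errors; map-gradient read-outs (curvature) are accurate to a
  few percent only after profile filtering, and degrade near the seed
  and the cut locus.
* The exact seed-ball initialization applies only to uniform costs;
  data-driven maps keep the larger source error.
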