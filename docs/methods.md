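# Methods

## The model

`velflow` fits a **time-varying velocity field** to a chronologically
ordered series of K ≥ 2 point sets whose rows are in one-to-one
correspondence.  The field v(x, t) is stored as N spatial vector-field
slices attached to uniformly spaced *integration points*
τ_i = i/(N − 1) in normalized time [0, 1]; each voxel of slice i holds a
D-vector in physical units per unit normalized time.  Numerical
integration of v along trajectories yields the deformable transform
Φ_{t0→t1} between *any* two continuous times in [0, 1], which is what makes
the fitted object a transformation model rather than a stack of pairwise
registrations: for smooth fields of moderate magnitude the mapping is
diffeomorphic (invertible, no folding), as the Jacobian and
inverse-consistency checks in the test suite verify on synthetic flows.

### Optimization

Starting from v ≡ 0, each iteration loops over the N integration points.
At τ_i:

1. The bracketing pair of series times [t_a, t_b] is located (interior
   ties resolve to the left interval; τ = 0 and τ = 1 use the first and
   last interval so the endpoint slices still receive updates).
2. Point set P_a is flowed forward from t_a to τ_i and P_b backward from
   t_b to τ_i under the *current* field.
3. The residuals r_j = x_j^{b→τ_i} − x_j^{a→τ_i}, anchored at the pair
   midpoints and divided by (t_b − t_a) to convert them to velocity
   units, are smoothed into a dense update field U_i by the weighted
   multilevel B-spline scattered-data approximation (below).
4. Slice i is updated: v_i ← v_i + δ·U_i with step size δ.

Midpoint anchoring symmetrizes the update between the forward- and
backward-warped sets; the 1/(t_b − t_a) scaling gives the update velocity
units so that integrating over the interval reproduces the full residual.
Only slice i is touched per integration point — temporal coupling arises
implicitly because the warps in step 2 traverse neighbouring slices.  The
fit is fully deterministic: there is no randomness anywhere in the
optimization.

The convergence statistic is the *average displacement error*: the mean
over integration points of the weighted mean residual norm.  The unweighted
mean and the per-slice median are logged alongside.  Early stopping
compares the change of a 10-iteration windowed mean of this statistic to
`convergence_tolerance`; the default tolerance 0 disables early stopping so
the full `max_iterations` budget always runs (fixed-budget usage).

### Defaults and units

| parameter | default | meaning |
|---|---|---|
| `n_integration_points` | 11 | velocity slices N over [0, 1] |
| `step_size` | 0.2 | update scale δ per integration point per iteration |
| `max_iterations` | 200 | fixed optimization budget |
| `convergence_tolerance` | 0 | windowed early-stop threshold (0 = off) |
| `integration_substeps_per_slice_interval` | 4 | midpoint-rule substeps |
| B-spline `order` / `base_mesh` / `levels` | 3 / 1 / 4 | regularizer mesh |

All coordinates, spacings and displacement errors are physical (one unit
throughout, e.g. µm); times are normalized.  Velocity slices and
displacement fields are stored as 32-bit floats — at atlas-scale grids
(hundreds of voxels per axis, N ≈ 11) the container then stays in the
low-gigabyte range.

## B-spline scattered-data approximation

The regularizer converts M weighted residual samples into a C^(order−1)
field on the grid.  Each level of the classic multilevel scheme computes
control values by a local weighted accumulation
(value_c = Σ_s w_s φ_cs² d_cs / Σ_s w_s φ_cs², where d_cs is the
one-sample minimum-norm solution φ_cs δ_s / Σ_{c'} φ_{c's}²), evaluates the
approximant, and fits the remaining residual on a mesh of doubled
resolution.  User confidence weights w_s enter every accumulation, and
uniform weight rescaling provably cancels.  Properties relied on elsewhere:

* **Linearity in the sample values** (exactly; tested to float tolerance).
* **Monotone anchor residual** in the number of levels, measured by exact
  spline evaluation at the anchors.
* **Interpolation limit**: a single sample is reproduced exactly at any
  level (the local formula coincides with the minimum-norm least-squares
  solution of the one-row interpolation system); dense samples are
  interpolated once the mesh outresolves the sample spacing.  Between
  scattered samples the approximant is smooth but *not* the global
  weighted-least-squares optimum — the scheme is local by design.

Anchors that leave the grid (warped midpoints can) are clamped to the
domain boundary rather than dropped, so no correspondence is silently lost.

## Numerical integration

Trajectories use a fixed-step midpoint (second-order Runge–Kutta) rule
with `integration_substeps_per_slice_interval` substeps per slice interval;
velocity is interpolated linearly in time between adjacent slices and
multilinearly in space, clamping out-of-domain queries to the boundary
(zero-padding would inject artificial velocity discontinuities at the
edge).  The scheme is *exact* for velocities constant in space and at most
linear in time — midpoint quadrature integrates linear integrands without
error — so its order of accuracy must be measured on space-dependent flows;
on the stationary linear flow v(x) = a(x − c), whose trajectories are
exponentials, the observed log–log error slope versus substep count is −2
as expected.  Image warping uses the pull-back convention: the displacement
integrated from the *output* time back to the *input* time indexes the
source intensities (linear or nearest-neighbour resampling).

Displacement inversion is the standard fixed-point iteration
u ← −d∘(id + u), stopped when the mean update norm falls below tolerance;
five consecutive increases of the update norm abort with a diagnostic
(deformations whose fixed-point map has Lipschitz constant above one cannot
be inverted this way).

## Temporal normalization

Developmental series sample age very unevenly, so chronological days are
log-transformed before min–max normalization: ratios of age map to
differences of normalized time, spreading the stages far more evenly.  For
the seven-stage mouse series the package places postnatal day d at
18.5 + d continuous days (birth at E18.5/P0) and caps the oldest stage at
28 postnatal days, giving (11.5, 13.5, 15.5, 18.5, 22.5, 32.5, 46.5).  Only
the 28-day cap is an established convention; the embryonic/postnatal
concatenation offset is a documented package choice, exposed as the
constant `EMBRYONIC_TERM_DAYS` and overridable by passing explicit days.

## Label sampling and virtual templates

Point sets are built from multi-label volumes by stratified per-label
sampling: boundary voxels (face adjacency — 6-connectivity in 3-D — with
background and the outside of the volume counting as "different") at
`contour_rate` (default 10%), interior voxels at `region_rate` (default
1%), `round(rate · count)` samples with a floor of one when the stratum is
non-empty.  Boundary points carry twice the interior weight by default.
Sampling is without replacement and deterministic given the seed.  Whether
rates should be applied per label or globally is not externally fixed;
per-label stratification is implemented because it guarantees every region
contributes points.  Rigid pre-alignment is reduced to its translational
part (shared-label centroid differences); rotation estimation is left out
as unnecessary for the synthetic verification pipeline.

Virtual templates at an unsampled time are plain voxelwise combinations of
temporally adjacent volumes warped to the target time — uniform mean or
inverse-temporal-distance weights with an exact-match short-circuit.  No
registration-based shape refinement is performed; the result is an
intensity average in the target space, not a sharpness-optimized template.

## What the synthetic generators emulate — and what they do not

`synthetic_fixtures` produces point-set series under analytic flows
(translation, rotation about the domain center, radial expansion — the
trajectory family of a stationary linear velocity field — and a temporal
sinusoid), with optional per-stage Gaussian jitter applied independently at
each time point to mimic per-stage annotation noise rather than trajectory
noise.  Label volumes are rasterized cubes/spheres; intensity images are
Gaussian blobs.  These fixtures give exact ground truth for recovery
tests, but they are simple, smooth, low-curvature motions on clean
geometry: passing them demonstrates that the optimization recovers fields
it can represent and that the integration/inversion machinery is
consistent.  It does not demonstrate robustness to anisotropic growth,
topology-adjacent label changes, registration error in the propagated
correspondences, or the sheer scale of real atlas series (10⁵–10⁶ points,
hundreds-of-voxels grids).

## Problem sizes used in the shipped evaluation

The test suite and `scripts/acceptance.py` run the full pipeline at desk
scale, chosen as the smallest sizes at which the properties are
meaningfully exercised: 64³ voxel grids (32³ for the virtual-template
case), 200–500 points, K = 2–4 stages, N = 3–11 integration points and
60–200 iterations.  Measured results at these sizes: zero-motion series
yield an exactly zero field; a two-voxel translation is recovered with
≈ 0.04% endpoint error; a 10%-per-unit-time radial expansion with ≈ 0.5%
of the mean displacement, inverse-consistency residual ≈ 10⁻³ voxels and
strictly positive Jacobian determinants; the affine scattered-data oracle
reproduces to < 10⁻³ of the field range.

## Known limitations

* Grids must be axis-aligned (identity direction); oblique volumes are
  rejected at load time and must be reoriented upstream.
* The fit assumes correspondences are given; it performs no matching.
* Fixed-point inversion fails for very large deformations (by design,
  with a diagnostic).
* The per-slice update is first-order coordinate descent; very large
  inter-stage displacements may need more iterations or a larger N.
* Intensity-driven estimation, geodesic-shooting formulations and
  registration-based template refinement are out of scope.
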