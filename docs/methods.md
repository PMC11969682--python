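# Methods

## The question and the experiment

Pteraspidiform heterostracan oral plates carry rows of small (~110 µm)
sharply pointed denticles whose cusps face rostrally — into the incoming
flow of a swimming, ram-ventilating animal.  The package tests a specific
functional hypothesis: that this orientation is an adaptation for
vortical cross-step filtration, i.e., that it generates recirculating
vortices in the spaces between denticles which would re-suspend food
particles.  The experiment is a 2×2×2 grid: geometry (idealized row /
shape-perturbed "empirical-like" row) × orientation (rostral / caudal
mirror, the null model) × inlet speed (0.05 / 0.5 m/s, spanning passive
to active swimming).  The hypothesis predicts orientation-dependent
recirculation; equivalence across orientations rejects it.

## Geometry

A denticle row is a simple closed polygon: a thin baseline slab
(thickness 2×10⁻⁵ m) carrying `n` asymmetric triangular denticles at
pitch `p` (default 1.25×10⁻⁴ m), base length 1.10×10⁻⁴ m, height
5.5×10⁻⁵ m, with the cusp tip overhanging the upstream gap by a fraction
(default 0.3) of the base length.  The overhang closes each
inter-denticle space into a flask-shaped cavity with a ~45 µm mouth —
the morphology relevant to vortex trapping.  Defaults give a 20-denticle
model of length L ≈ 2.5 mm; the empirical-like variant rescales x so
L targets 2.35 mm and multiplies per-denticle height, base and overhang
by independent lognormal factors (CV 0.25, seeded), emulating how
cross-section position varies along real denticle rows.  Denticle height
is not directly constrained by published measurements; half the denticle
length is consistent with figured aspect ratios and is an exposed
parameter.  Caudal models are exact mirror images (an involution that
preserves area).

The computational domain follows the published sizing rule: ≥3 L of
clear water upstream, ≥20 L downstream (10 L in the desk-scale preset,
see below), height 0.01 m (~20× the baseline–sample midline height V1 =
height/20).  Profiles are rasterized by cell-center point-in-polygon
tests onto a rectilinear grid: uniform spacing h near the body (fine
window = model extent padded by 0.2 mm in x, 0.1 mm above the profile)
and geometrically graded (ratio 1.12, capped at 2.5×10⁻⁴ m) in the far
field — the Cartesian analog of the original fine refinement region
inside a coarser domain mesh.  Rasterized solid area converges to the
polygon (shoelace) area with error bounded by h × perimeter.

## Flow model and solver

Steady 2D incompressible laminar flow of water (ρ = 998.2 kg/m³,
μ = 1.003×10⁻³ Pa·s).  Boundary conditions: uniform normal inflow U on
the upstream boundary; zero gauge pressure at the outlet; slip symmetry
("open") top; no-slip floor and model surface.  Reynolds numbers are
*reported* with the conventional ν = 10⁻⁶ m²/s (so U = 0.05 m/s,
L = 2.5 mm gives exactly Re = 125) while the simulation uses the
tabulated water properties (ν = 1.0048×10⁻⁶ m²/s); the distinction never
exceeds 0.5% and keeps both the printed Reynolds numbers and the
physical fluid exact.  All cases lie far below the turbulent threshold
(Re ≈ 2000), justifying the stationary laminar model.

The discretization is a staggered (MAC) arrangement on the rectilinear
grid with a stair-step solid mask: velocities on faces adjacent to solid
cells are zero, and tangential no-slip enters through antisymmetric
ghost values at half-cell distance (first-order accurate at walls).
Advection is first-order upwind — robust at the coarse-cell Péclet
numbers of the graded far field, at the cost of numerical diffusion.
The steady state is obtained by artificial-compressibility pseudo-time
iteration (∂p/∂τ = −c²∇·u, c = 2.5 U plus a viscous floor) with a local
time step per unknown from the combined advective–acoustic–viscous
stability limit (CFL 0.6).  Iteration stops when the normalized momentum
and continuity residuals fall below `convergence_tol` (10⁻⁶) or when the
drag force stalls (relative change < 0.1% over 1000 iterations with the
momentum residual below 100× the tolerance); non-convergence is reported
on the solution object, never raised.  The initial guess is a
boundary-layer-like profile, which removes most of the start-up
transient.

Drag per unit depth sums pressure over vertical solid faces and viscous
shear over horizontal faces, the latter with a two-point one-sided
quadratic fit (exact for a parabolic near-wall profile).  A
control-volume momentum-flux estimate (inlet/outlet momentum + pressure,
minus floor shear outside the model footprint) cross-checks the surface
sum on validation cases.

Validation contracts (all enforced in the test suite): Poiseuille
mid-channel profile within 2% of the closed form; Couette vorticity
−U/h within 2%; inlet/outlet flux balance within 0.1%; floor drag within
3% of 6μUℓ/h; control-volume vs analytic drag within 5%; solving the
mirrored geometry equals the x-reflection of the reversed-flow solve of
the original (an end-to-end symmetry oracle); velocity fields linear in
U within 1% in the Stokes regime; lid-driven-cavity primary-vortex
center stable under 2× refinement within 5% of the cavity side.

## Near-denticle metrics and recirculation

Edge denticles feel the finite length of the row; the first and last
`n_exclude` denticles (7 by default, 2 at desk scale, mirroring the
published 5–10 exclusion) are trimmed before any metric is computed.
The *near-denticle band* is the set of fluid cells within one denticle
height above the column-local solid top, restricted to the kept span.

Recirculation zones are connected components of reversed streamwise flow
(u < −ε·U) inside the band, labeled by inter-denticle gap.  The reversed
flow in the flask cavities peaks at O(10⁻³ U) while the converged
solver's velocity noise sits at O(10⁻⁵ U); the threshold ε = 10⁻⁴
separates the two by an order of magnitude each way and the zone counts
are insensitive to halving or doubling it.

The headline peak velocity/vorticity metrics sample the **recirculating
cells** of the band — the swirling flow inside and atop the sheltered
spaces, which is what the original pathline visualizations color — not
the boundary-layer shear grazing the denticle tips, which belongs to the
"undisturbed" overlying flow and exceeds the cavity flow by 2–3 decades.
Whole-band maxima are also reported (`peak_*_band`) for transparency.
Orders of magnitude are floor(log₁₀ |peak|).

## Decision rule

For each (geometry, inlet-speed) pair with both orientations converged:
`hypothesis_rejected` if both orientations recirculate in ≥90% of the
interior gaps and their velocity and vorticity orders of magnitude
match; `hypothesis_supported` if the rostral run covers ≥90% of gaps
while the caudal covers ≤10%; otherwise `inconclusive` (including any
unconverged run — never silently dropped).  The overall verdict is the
unanimous pair verdict, else `inconclusive`.  The order-of-magnitude
granularity deliberately matches the coarseness at which such
pattern-comparison results can honestly be stated.

## Problem sizes and the desk-scale preset

The default test and acceptance configuration (`scale="small"`) uses 10
denticles, margins (3 L, 10 L), trimming n_exclude = 2, and the full
0.01 m domain height; the 8-run grid solves in minutes on one CPU.  The
full preset (20 denticles, 20 L downstream, n_exclude = 7) is the
published configuration and runs unchanged, only slower.  The domain
height is *not* scaled down because the "flow above the denticles
remains undisturbed" check (a streamline seeded at 0.9× height must stay
straight within 1% of the height) is only meaningful when the floor
boundary layer's displacement thickness is small against the height.

Grid independence follows the published criterion: drag must change ≤5%
between successive refinements (near-body h = 2×10⁻⁵ → 10⁻⁵ → 5×10⁻⁶ m)
or domain extensions.  Drag meets this comfortably.  The *cavity
interior* metrics converge more slowly than drag: a stair-step mask at
h = 10⁻⁵ m leaves the ~40 µm cavity vortex only ~4 cells across, and the
peak cavity vorticity still changes by ~2× between h = 10⁻⁵ and
5×10⁻⁶ m.  Near-denticle magnitude metrics are therefore reported from
the finest grid of the independence sequence (h = 5×10⁻⁶ m); a 10⁻⁵ m
body-fitted triangular mesh (as in the original study) resolves those
cavities far better than a 10⁻⁵ m stair-step mask, so the finer Cartesian
grid is the like-for-like comparison.

## Known limitations

- The desk-scale row places its kept denticles in a thinner floor
  boundary layer than the 20-denticle model (the kept gaps sit at
  x ≈ 4–5 mm rather than 8–9 mm from the inlet), which raises local
  shear and cavity speeds by roughly 1.5–2×.  At 0.5 m/s this lifts the
  peak recirculating speed (~1.7×10⁻³ m/s) one decade above the
  published 2–8×10⁻⁴ m/s band; at 0.05 m/s all magnitudes agree.
- Stair-step masks resolve neither the cusp tip curvature nor the exact
  cavity volume; first-order upwinding damps the cavity vortices.  Both
  effects are conservative with respect to the hypothesis test, which
  compares orientations under identical numerics.
- The steady solver reports a drag-stalled state at Re = 1250 where a
  bluff-body wake could in reality be weakly unsteady; convergence mode
  is recorded per run.
- The synthetic "empirical-like" profiles emulate per-denticle size/shape
  variation but not true tomographic outlines (fused ridges, abraded
  cusps); passing tests demonstrate orientation-independence for the
  parametric morphology, not for any particular specimen.
- 2D sections cannot capture spanwise flow between denticle rows; this
  mirrors the original study's deliberate 2D scope.
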