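# Methods

## Model overview

The package simulates the water motion driven by a sessile olivooid polyp
that rhythmically expands and contracts its bowl-shaped subumbrella inside a
rigid periderm. Three modelling commitments define everything else:

1. **Creeping flow.** At the organism's scale (sub-millimetre openings,
   intake speeds of order 10 µm/s) the Reynolds number is far below one, so
   the inertial terms of the Navier–Stokes equations are dropped entirely.
   Each instant is an independent stationary Stokes problem: the field is a
   function of the instantaneous geometry and wall velocity only
   (quasi-steadiness), and it is exactly linear in the wall velocity.
2. **Prescribed kinematics.** The subumbrella is not an elastic structure;
   its wall displacement is imposed directly (radial component only, axial
   and azimuthal displacements identically zero). Muscle mechanics,
   mesogleal elasticity and internal anatomy are outside the model.
3. **Axisymmetry.** The tetraradial periderm with its twelve apertural lobes
   is reduced to a body of revolution in cylindrical coordinates (r, z),
   z = 0 at the sea floor, aperture up. The 20 × 10 × 10 mm cuboid
   computational domain reduces to a cylinder of radius 5 mm and height
   10 mm. The pagoda form is near-axisymmetric, and this is the only
   desk-scale faithful reduction; azimuthal structure (lobes, ridges) is
   deliberately sacrificed.

All lengths are mm, times s, velocities mm/s, so reported speeds are on the
natural scale of the organism.

## Geometry (the synthetic-data generator)

The geometry module plays the role that a fossil-derived 3-D surface model
plays in a scanned-specimen workflow; its defaults are the study conditions.

* Periderm: height 2.0 mm, basal radius 0.3 mm (0.6 mm width), inserted
  0.18 mm into the sediment (exposed height 1.82 mm = 2.0 − 0.18), tapering
  to an aperture radius of 0.1 mm. The taper is a power law
  r(h) = R_b − (R_b − R_a)(h/H)^p with p = 5, which stays near the basal
  radius over most of the height and narrows sharply near the tip — a smooth
  pagoda. Annular ridges are available as a sinusoidal perturbation
  (`ridge_amplitude`, default 0: the ridge geometry is not quantified in the
  source material).
* Subumbrella: a bowl 0.7 mm tall hanging from the aperture plane, apex
  anchored at z = 1.12 mm, widest (0.12 mm radius) at mid-height, narrowing
  to the mouth (opening radius 0.05 mm) at the rim. The two quoted figures
  for the bowl's width in the source material are mutually inconsistent, so
  both `subumbrella_max_radius` and `opening_radius` are configuration
  parameters, not hard-coded truths.
* The interior between bowl and periderm is solid (the polyp body): the only
  water inside the periderm is the subumbrellar cavity, which communicates
  with the exterior solely through the mouth at the aperture. This makes the
  aperture flux exactly balance the cavity volume rate — the model's central
  bookkeeping identity — where an annular gap between rim and periderm would
  break it.

Rasterization marks solid cells (indicator χ), assigns the radial surface
velocity of the nearest subumbrella surface point to wall cells (within a
2.5-cell band; rigid periderm and deep body cells are motionless), and
signals under-resolution when the cavity or its mouth is not carried by the
grid. Two numerical choices matter:

* Surface velocities are sampled against the rest-state surface
  parametrization. The motion is radial-only, so the z-parametrization is
  unchanged and the lookup is exact in z; it also makes the discrete unit
  problem identical whenever the rasterized geometry is, which the pipeline
  exploits (below).
* At penalized faces the radial velocity is interpolated via the
  axisymmetric flux density r·u rather than u itself, so the volume swept by
  the rasterized staircase matches the kinematic swept volume. Measured
  flux/volume balance on the default grid: 0.97–1.00.

## Kinematics

Wall displacement: Δr(z, t) = c · A(z) · s(t).

* **A(z)** — cubic spline through control points, clamped to zero slope and
  value at the apex (the bowl hangs from a fixed anchor), zero outside the
  bowl span. Defaults: +0.05 mm at mid-bowl, −0.02 mm at the rim. Outward
  mid-bowl motion inflates the cavity (suction through the aperture) while
  the inward rim motion narrows the mouth over the expansion — both features
  of the described behaviour. The displacement table used by the original
  study sits in an inaccessible supplement; these control points are the
  package's reconstruction.
* **s(t)** — rises 0 → 1 over the expansion phase and returns 1 → 0 over the
  contraction. The rate ds/dt is a Beta(a, b) bump per phase with a + b = 6,
  zero at the phase endpoints (C¹ ramp), with its mode at `peak_fraction`
  of the phase: a = 1 + 4f, b = 5 − 4f. Defaults f_exp = 0.6 and
  f_con = 0.5, anchored to the observed peak times (1.8 s into a 3 s
  expansion; 3.5 s in the 3–4 s contraction window). All scenarios are
  time-stretches of this one shape, so peak rates — and, by linearity, peak
  intake speeds — scale exactly as 1/T_exp.
* **c (amplitude_scale)** — dimensionless, default 0.076488, frozen once
  during development so the 1 s : 1 s scenario's expansion-phase peak speed
  at the z = 2.05 mm cut point lands on 0.0155 (the creeping-flow response
  is proportional to c, so this is a single linear rescaling). At this
  amplitude the maximal wall displacement is ≈ 4 µm.

Scenario shorthand "1:1", "2:1", "3:1", "4:1" maps to expansion durations of
1–4 s with the contraction fixed at 1 s.

## Flow solver

Stationary axisymmetric Stokes equations with a Brinkman penalization term
(μ/η) χ (u − U) driving penalized cells toward the prescribed solid velocity
U; η defaults to 1e-8 s (penalization errors ≈ 1e-5 of the peak wall speed,
threshold 1 %).

Discretization: uniform staggered MAC grid, default 121 × 241 cells over
5 × 10 mm (≈ 41 µm cells); u_r on r-faces, u_z on z-faces, p at centers;
the full axisymmetric operator including the 1/r metric terms. One sparse
saddle-point system per snapshot, solved directly (SuperLU). Boundary
conditions: symmetry at r = 0; no-slip floor; zero normal traction
(σ_nn = 0, pressure gauge 0) on the open top and lateral boundaries — the
source setup says only "open boundaries", and zero traction is the standard
realization. Inside solid cells the continuity row is replaced by p = 0;
fluid cells satisfy the discrete divergence constraint to solver precision
(~1e-14 s⁻¹ measured).

Validation oracles: the analytic expanding-sphere source field
u = ȧ (a/r)² (radial speed within 4 % at r = 2a on a 61 × 121 grid, 10 %
asserted), exact linearity and kinematic reversibility (≤ 1e-10 relative),
and the flux/volume balance above.

## Pipeline and memoization

A scenario run samples the cycle at 0.05 s intervals (an output-resolution
choice, not a stability constraint — the physics is quasi-steady; 0.01 s is
available via configuration and is used automatically to refine peak
times). For each snapshot the pipeline rasterizes the displaced geometry,
solves for a unit ramp rate, and scales the field by the instantaneous
rate. Unit solves are memoized on the byte content of (mask, unit
velocities, grid, solver constants): identical snapshots — including across
scenarios, which share the ramp's s-path — are solved once. This is pure
memoization; recomputing any snapshot in isolation reproduces it
bit-for-bit, and reruns are byte-identical.

At the calibrated amplitude the wall displacement (≈ 4 µm) is smaller than a
grid cell, so the rasterized geometry is the same at every snapshot and each
scenario reduces to one unit solve: speed traces are |ds/dt| times a fixed
spatial response. Consequences worth knowing: the contraction-phase traces
of the four scenarios are exactly identical (contraction is always the same
1 s stroke), the cut-point peak times coincide exactly with the ramp-rate
peaks, and sub-cell geometry changes (e.g. the mouth narrowing) influence
the kinematic record but not the rasterized flow problem. Larger amplitudes
make the mask evolve and are exercised in the test suite.

## Post-processing

* **Maxima table** — per cut point and scenario, the phase-tagged maximum
  speed with 0.01 s peak refinement.
* **Vorticity** — ω_φ = ∂u_r/∂z − ∂u_z/∂r by centered differences at cell
  centers; the dimensionless copy is ω* = ω_φ · T_scale with T_scale = 1 s
  by default (the nondimensionalization used for the original colour maps is
  undefined, so the scale is configurable).
* **Vortex tracking** — signed connected regions with |ω*| ≥ threshold
  (default 2e-5), restricted to the water outside the periderm, linked frame
  to frame by footprint overlap; per phase the strongest structure is
  labelled *main* and the strongest opposite-signed coexisting structure
  *secondary*. Events: formation, floor contact (footprint reaches the
  bottom), separation, and replacement (an opposite-signed main appears
  after the phase turnover). Because the quasi-steady vorticity pattern
  scales with the ramp rate instead of advecting, a wall-attached structure
  "separates" in the level-set sense: its footprint — pruned from the
  weakest cells inward as the stroke decelerates — either clears the
  wall-distance threshold δ (default two grid cells) or fades out entirely
  while frames continue; both routes emit the event, the second only for
  structures that had previously touched the δ-zone. The detection
  threshold was frozen once so that the canonical 3:1 run detects the two
  dominant opposite-signed expansion structures and resolves the full event
  chronology; thresholds affect visualization and event timing, never the
  velocity physics.
* **Reynolds number** — ρUL/μ from the simulated peak speed and the
  configured opening diameter; the canonical runs sit well below one,
  consistent with the inertia-free model.
* **Grid sensitivity** — reruns the 3:1 scenario over a refinement ladder
  (default factor √2 per level, the lower end of the √2–2 range, closest in
  spirit to tetrahedral element-growth steps) and reports the average over
  snapshots of the mean relative cut-point-speed difference between
  consecutive levels, flagging the coarsest level meeting the ≤ 10 %
  mesh-independence rule. Default grid vs √2 refinement: 5.9 %.

## What the generator does and does not emulate

The geometry/kinematics modules stand in for an unavailable fossil-derived
surface model and its displacement table. They reproduce the published
dimensions, phase structure, and motion character, but real data differ in
ways the tests cannot probe: tetraradial lobes and annular ridges (dropped
by axisymmetry), the true displacement amplitudes (reconstructed up to the
calibrated scale), internal anatomy (manubrium, tentacles, stalk — all
omitted), ambient currents and neighbours (the domain is hydrostatic and
contains one polyp). Passing tests therefore demonstrate the fidelity of
the solver and the internal consistency of the reconstruction, not
agreement with a specific fossil individual.

## Numerical choices and degenerate inputs

* Direct sparse factorization per unit problem: robust at any amplitude, no
  time-step stability constraints, deterministic.
* Cut points are sampled by component-wise bilinear interpolation on the
  staggered grids, clamped at the axis (u_r has a node at r = 0; u_z is even
  across the axis). Sampling positions inside the solid are rejected.
* Geometry validation rejects non-physical states: bowl/periderm
  intersection (0.005 mm clearance), axis crossing, displacement outside the
  periderm, non-positive phase durations, duplicate spline nodes, sampling
  outside the cycle.
* Zero-rate instants (phase endpoints) produce exactly zero fields via the
  linear scaling; motionless snapshots are skipped when averaging relative
  differences in the sensitivity report.
* The rasterizer requires the cavity (≥ 4 cells) and its mouth (≥ 1 cell
  column) to be resolved and raises otherwise; the default grid resolves the
  mouth with one cell column and the next refinement with two, which is the
  main contributor to the 5.9 % sensitivity figure.

## Known limitations

* One-way coupling only: the fluid does not push back on the polyp, per the
  prescribed-kinematics design.
* The quasi-steady model has no vortex advection or wake memory; event
  timing for separations reflects threshold crossings of a rate-scaled
  pattern, so separation times carry the detection threshold's imprint
  (ordering and phase placement are robust, exact instants are not).
* The far-field decay above the aperture follows the ~z⁻²–z⁻³ law of a
  low-Reynolds source near a wall; no parameter choice can make the intake
  current both fast at z = 2.05 mm and negligible at z = 2.2 mm, a
  constraint worth keeping in mind when comparing against reported
  feeding-range thresholds.
* Axisymmetry precludes any azimuthal structure in the flow.
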