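# Methods

`stentflow` studies how the placement geometry of a branch stent-graft —
its tilt angle against the aorta, how deep its tip protrudes into the
aortic lumen, and its diameter — controls blood flow into the branch
artery after fenestrated/branched endovascular aneurysm repair.  It couples
a parametric planar flow model with the small-sample clinical statistics
used to compare per-artery case records.

## The flow model

### Planar reduction

The physical system is a 3D tube junction.  This package models the plane
that contains both vessel axes: a straight channel of width `D1` (the
aortic stent lumen) with a branch channel of width `D2` leaving through one
wall at tilt angle `theta`, measured from the upstream aortic axis to the
branch outward axis.  `theta < 90°` points the branch tip against the
oncoming flow, `theta > 90°` with it.  A protruding stent adds two solid
walls of thickness `wall_thickness` (default 0.5 mm, a typical covered
stent-graft, rendered at least one grid cell thick) extending `entry_depth`
into the aortic lumen along the branch axis.  The beveled variant removes
the upstream-facing protruding wall down to the aortic wall plane, leaving
the downstream wall at full protrusion so the tip lumen opens toward the
oncoming flow — the planar analogue of cutting the tube end parallel to
the aortic wall.

The in-plane mechanisms the observables are built on — tip obstruction,
the recirculation pocket at the ostium, direction-dependent reflux, the
ram-scoop effect of the beveled tip — survive this reduction.  Absolute 3D
magnitudes do not, and are never asserted.

### Governing equations and discretization

Steady incompressible Newtonian flow (blood: density 1055 kg/m³, viscosity
0.0035 kg/(m·s)), rigid no-slip walls, plug inlet velocity (0.8 m/s
default), and one fixed gauge pressure on *both* outlets (13,300 Pa,
reported additively).  With equal outlet pressures the aorta/branch flow
split is an emergent result of the solve — this split, the signed branch
mass flux per unit depth, is the primary observable.  Positive flux is
outflow toward the branch artery; negative is reflux.

The solver is a staggered-grid (MAC) finite-volume SIMPLE loop: hybrid
central/upwind convective fluxes (Patankar), implicit under-relaxed
momentum predictor (Jacobi sweeps, default 3 per outer iteration, momentum
relaxation 0.7), and a pressure-correction Poisson equation solved by
sparse direct factorization every outer iteration (pressure relaxation
0.3).  Because the correction is solved to machine precision, the corrected
field satisfies discrete continuity essentially exactly; the convergence
criterion (default 1e-5) is applied to the normalized mass residual of the
momentum predictor and to both momentum residuals.  Iteration order is
fixed and there is no randomness: identical inputs give bit-identical
residual histories.

Geometry is rasterized on a uniform Cartesian grid (cell size `h`, default
`D2/8`) by cell-center point-in-region predicates.  Blocked faces carry
zero velocity.  For wall-tangential diffusion the no-slip surface is placed
at its *true* analytic position: each wall-adjacent link measures its
distance to the surface by bisection on the analytic fluid predicate and
uses that distance in the diffusive conductance.  Grid-aligned walls
recover the classic half-cell mirror exactly; inclined (staircase) walls
lose the systematic narrowing that a plain first-order treatment inflicts
on them.  This matters because the experiments compare axis-aligned
(θ = 90°) against inclined branches: with plain first-order walls the
aligned branch sees less viscous resistance than any inclined one, an
artifact comparable in size to several of the trends of interest.
Residual first-order effects remain in the convective staircase and
shrink under refinement.

### Reynolds scaling

The nominal channel Reynolds number (ρ·V·D1/μ ≈ 7.2e3 at D1 = 30 mm,
0.8 m/s) is transitional; resolving it would need a turbulence closure the
model deliberately does not include.  All sweeps therefore run laminar at a
reduced Reynolds number, default 200 (`scale_reynolds` rescales only the
viscosity; densities and inlet speed stay physical so fluxes keep their
scale).  Trend robustness is additionally checked at Re = 400.  Run logs
record both the scaled and nominal Reynolds numbers.

What the scaling preserves and what it does not, as measured by the
package's own grid studies:

* Preserved: the protruding-tip mechanisms.  A stent tip standing in the
  oncoming stream at θ ≤ 90° drives strong reflux that deepens with entry
  depth and diameter; a downstream-tilted tip (large θ) rams flow into the
  branch; the beveled tip converts the canonical reflux case to outflow.
  These are inertial, geometry-driven, and robust to the scaling.
* Not preserved: the flush (no-stent) junction's angle preference.  At
  scaled Re the branch inflow is nearly creeping (branch Reynolds number of
  order 10): branch flow is set by the aortic pressure gradient and branch
  conduit resistance, which are angle-independent, so the flush-junction
  flux is nearly flat in θ (and the θ = 90° junction, with the geometrically
  shortest entry path, is mildly favored).  The full-Re, 3D behavior —
  outflow increasing with tilt angle beyond 90° — is a momentum-capture
  effect that does not survive the viscosity rescaling.  Grid refinement
  (h = D2/8 → D2/16) does not restore it, so it is a property of the scaled
  model rather than of the grid.  The sweep that probes it is retained and
  reported, with this limitation documented, and the reflux-to-outflow
  transition of the *stented* configurations sits somewhat above the
  full-Re threshold (between 105° and 135° at Re = 200 rather than near
  100°).

### Observables

* **Branch mass flux** ρ·Σ(u·n)·h over the branch outlet staircase,
  kg/(m·s) per unit depth; classification into outflow/reflux with a dead
  band of 1e-3 of the inlet flux (discrete solutions never produce an exact
  zero).  An optional pseudo-3D conversion (×π·D2/4) exists for reporting
  only.
* **Wall shear stress** μ|∂u_t/∂n| by a one-sided first-order difference at
  each wall face (tangential cell-center velocity over the half-cell
  distance), profiled along the branch-axis coordinate; summarized as the
  mean over the branch wall.  The mean-over-branch-wall summary is a
  package choice; the clinical literature rarely states which summary it
  prints.
* **Recirculation area**: fluid cells whose axial velocity opposes the
  inlet direction, inside a window of ±2·D2 around the ostium across the
  full aortic width (the window is a package definition; vortex regions
  are shown but never defined in the clinical sources).

### Numerical choices and degenerate inputs

Under-relaxation 0.7/0.3, tolerance 1e-5, iteration cap 8000 in the sweep
profile (20000 default).  Divergence (mass residual growing 1e3× past its
initial value) raises an error naming the iteration; the sweep driver then
retries deterministically with 0.6× relaxation factors and a doubled
iteration cap, twice at most.  Faces that lose their diagonal (all
neighbors beyond an outlet with net inflow) are floored at the diffusive
conductance.  Conduit lengths must be at least five widths so inflow and
outflow are developed; the default scene uses the full clinical lengths
(L1 = 200 mm, L2 = 100 mm) and the coarse sweep profile shortens them to
the minimum (L1 = 150 mm, L2 = 5·D2) to keep a full sweep suite inside a
desktop time budget — sweeps compare configurations within one profile,
never across profiles.

## The synthetic cohort and the statistics stage

The clinical stage consumes per-artery records: tilt angle, entry depth,
branch and aortic diameter, simulated flow, follow-up patency.  The
packaged table carries the six-patient, twelve-artery cohort (four
occluded arteries).  Per-artery flows are not part of that record,
only the grouping they induce; `assign_reconstructed_flows` therefore
attaches clearly-labeled synthetic flows that realize that grouping (the
four occluded arteries plus the two smallest-angle patent arteries fall
below the median).  Only the induced ordering matters to every statistic
downstream; magnitudes sit on the printed kg/s scale (cohort median
0.005 kg/s) for report formatting.

`generate_cohort` draws fully synthetic cohorts: half the angles from a
low group (mean 90°), half from a high group (mean 125°), common SD 12°
(centers and spread anchored to the clinical tables); depth ~ N(7, 2) mm;
diameter ~ N(5, 0.7) mm; flow = gain·tanh((θ−97.5°)/12°) modulated weakly
by depth and diameter, plus N(0, 0.001 kg/s) noise; negative flow marks
occlusion.  The tanh response mirrors the saturating reflux-to-outflow
transition the solver produces; `fit_surrogate` calibrates the same form
directly on a sweep table and refuses any fit whose sign disagrees with
the solver on a calibration row.  What the generator does *not* emulate:
anatomical correlation between the two arteries of one patient,
measurement error in CT-derived angles, and any flow dependence beyond the
three geometric parameters — so passing tests say the analysis pipeline is
calibrated and sensitive, not that real cohorts behave this way.

The analysis itself: median split of the cohort by flow (requires an even
count and untied flows — the clinical cohort splits 6/6), then per
variable a Lilliefors-type Kolmogorov–Smirnov normality gate on both
groups (statistic against a normal with the sample's own moments, p by
seeded Monte Carlo, 2000 replicates by default); both normal → pooled
Student t, otherwise the exact Mann–Whitney U.  The exact null
distribution is computed by the standard counting recursion and is the
point of the implementation: at six per group the coarse exact null is
what produces the printed p = 0.004 for the tilt angle (U = 1,
p = 2·2/924).  Cross-sample ties fall back to the tie-corrected normal
approximation with a warning; above n1+n2 = 25 the continuity-corrected
normal approximation is used.  Cohen's d uses the pooled SD with a seeded
bootstrap CI (10⁴ replicates).  Group summaries are median (Q1, Q3) with
type-6 quantiles, the convention of common clinical statistics software;
quartiles are convention-sensitive and are reported, not asserted.

A note on the median-split design: when flow genuinely increases with
angle, splitting at the flow median produces angle-ordered groups, so the
measured between-group separation exceeds the generative effect size and
the pipeline's power is bounded below by the independent-two-sample power
at the same effect.  Calibration is therefore checked where it is
well-posed — on null cohorts whose flow is pure noise, where the split is
independent of the covariates and the type-I rate must sit near α.

## Known limitations

* Planar, steady, rigid-wall, laminar at reduced Re: magnitudes are not
  3D-comparable; pulsatility and wall compliance are out of scope.
* The flush-junction angle trend at full Re is not reproduced at scaled Re
  (see above); the stented transition angle sits above its full-Re value.
* First-order convective staircase effects leave a few per cent of
  configuration-to-configuration scatter at the default grid.
* Quartile conventions and Cohen's d definitions vary across clinical
  software; only medians and exact-test p-values are treated as sharp.
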