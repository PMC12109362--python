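# stentflow

Desk-scale hemodynamics of branched stent-grafts after fenestrated/branched
endovascular aneurysm repair (F/B EVAR).

After F/B EVAR, the branch stent that feeds a renal artery inevitably
protrudes a short distance into the aortic stent lumen.  Whether blood then
actually flows *out* into the renal artery — or is drawn *back* from it
(reflux), a state associated with low wall shear stress, thrombosis and
renal-branch occlusion — depends on three placement parameters: the tilt
angle θ between the aortic axis and the branch stent, the entry depth L of
the protruding tip, and the branch stent diameter D2.  `stentflow` is for
vascular-biomechanics researchers who want a fully scripted, testable
version of that parameter study plus the clinical-cohort statistics that go
with it.

The package has two halves:

1. **Flow model** — a parametric planar (symmetry-plane) model of the
   aortic conduit with a protruding branch stent, solved as steady
   incompressible Newtonian flow (ρ = 1055 kg/m³, μ = 0.0035 kg/(m·s),
   plug inlet 0.8 m/s, equal fixed pressure on both outlets) with a
   staggered-grid finite-volume SIMPLE scheme.  The signed branch mass
   flux per unit depth,

       q_b = ρ ∮ (u·n) dℓ   over the branch outlet,

   is the primary observable: q_b > 0 is outflow, q_b < 0 is reflux.  Wall
   shear stress τ_w = μ|∂u_t/∂n| and the recirculation area near the
   ostium are profiled alongside.  Runs are laminar at a reduced Reynolds
   number (default 200; the physiological ≈ 7.2e3 is transitional), so
   flow *directions and monotone trends* are the meaningful outputs, not
   3D magnitudes.

2. **Case statistics** — per-artery records (twelve renal arteries of a
   six-patient cohort ship as a packaged fixture) are split at the median
   flow; each geometric variable is compared between the low- and
   high-flow groups with a Kolmogorov–Smirnov(-Lilliefors) normality gate
   choosing between the pooled Student t test and an **exact**
   Mann–Whitney U test whose null distribution is computed by the counting
   recursion — at n = 6 + 6 the exact null is what makes the printed
   p-values reproducible.  Cohen's d with bootstrap CIs and median (Q1,
   Q3) summaries complete the report.  A synthetic-cohort generator with a
   monotone angle→flow response calibrates type-I error and power of the
   whole pipeline.

## Worked example

```python
import stentflow as sf
from stentflow import postprocess as pp
from stentflow import sweeps

# canonical reflux case: right-angle branch, 15 mm entry depth
row = sweeps.run_single(theta=90, entry_depth=15, D2=8,
                        profile=sweeps.fast_profile())
print(f"{row['mass_flux']:+.3f} kg/(m s)  {row['classification']}")

# the beveled-tip modification of the same case
pair = sweeps.compare_bevel(90, 15, 8, profile=sweeps.fast_profile())
print(pair.table[["variant", "mass_flux", "classification"]])
```

```
-1.222 kg/(m s)  reflux
    variant  mass_flux classification
0  original  -1.222335         reflux
1   beveled   5.605374        outflow
```

The unmodified right-angle stent refluxes (−1.22 kg/(m·s) per unit depth
drawn back from the renal side; this configuration is physically unsteady
at the working Reynolds number, so the solver reports the cycle-averaged
field); cutting the tip so its lumen opens toward the oncoming flow flips
the same geometry to strong outflow (+5.61) — the beveled-tip design
rescues the worst configuration.

The clinical stage from the packaged cohort:

```python
from stentflow import casestats, cohort
records = cohort.assign_reconstructed_flows(cohort.load_clinical_cases())
comps, table = casestats.compare_groups(records)
print(casestats.format_report(comps))
```

```
Variable          High flow (n=6)         Low flow (n=6)           Cohen d       p
tilt_angle        126.9 (115.5, 133.8)    86.5 (79.8, 104.3)          2.86   0.001
entry_depth       8.2 (4.7, 9.7)          6.2 (5.5, 7.6)              0.43   0.475
branch_diameter   5.0 (4.1, 5.6)          5.3 (3.9, 5.6)             -0.13   0.825
```

Tilt angle separates the high- and low-flow arteries decisively (the
high-flow median is 126.9° versus 86.5°; the exact Mann–Whitney U on these
groups is U = 1, p = 0.004); entry depth and diameter do not.

A CLI mirrors the library:

```bash
stentflow sweep angle-depth --fast --out angle_depth.csv
stentflow sweep bevel --theta 90 --depth 15
stentflow stats compare --cases my_cases.csv
stentflow fixtures export --with-flows
stentflow cohort generate --seed 3 --out cohort.csv
```

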