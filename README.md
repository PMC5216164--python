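# seegplan

Automated multiple-trajectory planning for stereo-electroencephalography
(SEEG) depth-electrode implantation, operating on triangle-mesh anatomy.

In SEEG for refractory epilepsy, 7–12 straight depth electrodes are drilled
through the skull to intracerebral targets chosen by a neurosurgeon.  A safe
plan must keep every electrode away from blood vessels, avoid piercing
sulci, enter the skull at a drillable angle through an admissible region,
sample as much seizure-generating grey matter as possible, and keep the
electrodes far enough apart from one another.  `seegplan` automates this:
given surface meshes of the skull (with an admissible entry template),
vessels, sulci and a two-surface grey-matter model, plus a list of named
target points — all co-registered, in millimetres — it returns one
conflict-free trajectory per target.

## Method

For target `T_i` every vertex `E` of the skull entry template is a candidate
entry.  Hard constraints prune first: trajectory length `|E − T_i| <
d_length` (80 mm) and entry angle vs. the skull normal `< d_angle` (25°);
trajectories intersecting any artery, vein or sulcus are then removed using
per-structure bounding-volume hierarchies (BVHs) built from 30-bit Morton
codes, one triangle per leaf.  Each survivor is scored twice:

* **Risk** — the distance to the nearest vessel `f_crit(x)` is evaluated at
  128 evenly spaced points via best-first BVH traversal, accumulated as
  `S_crit = ∫ d_risk − clamp(f_crit(x), d_safety, d_risk) dx` and normalised
  to `R = S_crit / ((d_risk − d_safety)·length) ∈ [0, 1]`.  Any sample
  closer than the safety margin `d_safety` (3 mm) forces `R = 1`; a
  trajectory never nearer than the risk zone `d_risk` (10 mm) scores 0.
* **GM–WM ratio** — `J = 10` electrode contacts sit at 6 mm intervals from
  the tip; each contributes three axial points `c_j` and `c_j ± c_r`
  (`c_r = 1.2` mm).  `G` is the fraction of the 30 points with negative
  signed distance to the grey-matter shell (inside pial, outside white).

Candidates are **stratified-ranked**: sorted into `K = 10` equal-width risk
bins and ordered by descending `G` within each bin, trading at most one bin
width (0.1) of risk for better grey-matter sampling.  The multi-trajectory
planner then minimises the mean risk subject to every pair of electrodes
keeping a minimum distance `D > d_traj` (10 mm), using a depth-first search
over targets with dynamic-programming pools of low-risk partial plans:
conflicts are resolved by reviving the best unused alternative sub-plan or
advancing a conflicting electrode to its next-ranked candidate.

Because patient segmentations cannot be shipped, the package includes a
seeded phantom generator (`seegplan.phantom`) that emulates the study
inputs — a quasi-spherical skull whose template exposes 2000–10000 entry
vertices, tubular vessels of 0.5–2 mm radius, folded sulcal sheets, a
nested 70/55 mm grey-matter shell and separated deep targets — with known
analytic ground truth for testing.

## Worked example

`python examples/02_plan_phantom.py` generates a four-target phantom and
plans it:

```
phantom: 2273 admissible entry vertices, 6 vessels, 3 sulci, 4 targets
  T1: template_vertices=2273 -> after_length_angle=14 -> after_intersection=14 -> ranked=14
  ...
plan mean risk 0.0497, conflicts resolved 0
  target rank   length   angle    risk GM ratio
      T1    1    22.4mm   24.3°   0.000    0.133
      T2    1    23.6mm   24.4°   0.000    0.167
      T3    1    26.9mm   23.6°   0.199    0.200
      T4    1    29.4mm   23.6°   0.000    0.233
```

Per target the log shows the staged narrowing of the entry set (hard
constraints, then intersection rejection); the table lists the four
quantitative measures of each selected electrode.  `risk 0.199` means
target T3's best trajectory spends part of its length between 3 and 10 mm
from a vessel; all pairwise electrode distances exceed 10 mm.
`examples/03_conflict_resolution.py` shows the planner resolving a forced
electrode conflict that independent per-target planning cannot.

The same pipeline is scriptable from a shell:

```bash
seegplan phantom --seed 11 -o scene/
seegplan plan scene/ -o plan/            # plan.json + per-electrode profiles
seegplan evaluate scene/ plan/plan.json  # independent recomputation
```

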