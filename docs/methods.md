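# Methods

## Problem and model

One SEEG electrode is a straight segment from a skull entry point `E` to an
intracerebral target `T`.  A trajectory is feasible when it is shorter than
the longest available electrode (`d_length = 80` mm), enters within the
drillable angle of the skull normal (`d_angle = 25°`), and intersects no
artery, vein or sulcus.  Feasible trajectories are scored by a normalised
cumulative vessel-proximity risk `R ∈ [0, 1]` and a grey-matter sampling
ratio `G ∈ [0, 1]`; a plan for `N` targets minimises the mean risk subject
to all pairwise inter-electrode distances exceeding `d_traj = 10` mm.

All geometry lives in one co-registered millimetre frame.  Registration of
a generic entry template to the patient skull, and all image segmentation,
are upstream of this package: inputs are meshes and points already in
scene space.  The entry-angle normal is taken from the template mesh (the
entry vertices live on it), not the patient skull — one of the two is
needed and the template is the surface being searched.

### Risk score

Along the trajectory, sampled at `n_samples = 128` evenly spaced points,
the nearest-vessel distance `f_crit(x)` (vessels only — sulci gate the
intersection test but carry no proximity risk) is accumulated as

    S_crit = ∫ d_risk − clamp(f_crit(x), d_safety, d_risk) dx
    R      = S_crit / ((d_risk − d_safety) · length)

with `R = 1` forced outright when any sample falls below `d_safety`.  The
clamped integrand is the only form consistent with both stated anchors
(`R = 0` when `f_crit ≥ d_risk` everywhere, `R = 1` at `f_crit = d_safety`);
an unclamped "literal" variant that omits the lower clamp is available via
`PlanningConfig(risk_integrand="literal")` for comparison, and its value is
not confined to [0, 1].  Quadrature is the composite trapezoid over the 128
samples, the minimal rule consistent with sampling an integral; the safety
short-circuit is likewise evaluated at the samples only (no continuous
minimum over the segment), so a vessel thinner than the ~0.5 mm sample
spacing could in principle slip between samples — `n_samples` is
configurable to tighten this.

### GM–WM ratio

`J = 10` contact centres sit at `(j−1) · 6` mm from the tip `T` toward `E`;
each contributes three evaluation points offset `±c_r = 1.2` mm **along the
trajectory axis** (the electrode's physical extent — not radially).  `G` is
the fraction of the `3J` points whose signed shell distance

    f_gm(p) = max(sd_outer(p), −sd_inner(p))

is negative, i.e. inside the pial surface and outside the white surface.
Points exactly on a surface (`f_gm = 0`) count as non-GM, and contacts
beyond the entry point of a short trajectory are evaluated where they lie
(outside the head, hence non-GM) rather than clipped.

### Stratified ranking

Candidates are sorted into `K = 10` equal-width risk bins over [0, 1]
(`R = 1` in the last bin) and ordered by descending `G` within each bin, so
rank 1 has the best grey-matter sampling within the lowest occupied risk
bin.  Binning is by risk *value*: it matches the [0, 1] normalisation and
bounds the risk premium paid for grey matter by one bin width, `1/K`.  All
sorting ties break by entry-vertex index, which makes the whole pipeline
deterministic and underpins the order-independence property of the
multi-target search.

### Multi-trajectory search

Targets are added one at a time.  The depth-`n` pool (a priority queue of
partial plans keyed by mean risk, ties lexicographic) is seeded with the
incumbent best `(n−1)`-plan extended by the new target's rank-1 candidate.
While the pool minimum has a conflict `(i, n)` — detected by exact
segment-segment distance, pairs involving the newest electrode by
construction — three successors are enqueued: the best unused alternative
partial plan popped (destructively) from the depth-`i` pool and re-extended
greedily with each intermediate target's best non-conflicting candidate;
the variant advancing `a_n → a_n + 1`; and the variant advancing
`a_i → a_i + 1`.  The third successor is this package's addition: pools
are only populated by conflict events, so the depth-`i` pool can be empty
(always true for `i = 1`), and without it feasible instances whose
resolution requires moving an early electrode would be unreachable and the
result would depend on target order.  It only adds members to a best-first
pool, so whenever the first two successors suffice the same plan is found.
The first conflict-free pool minimum at depth `N` is returned.  Global
optimality is not claimed; the test suite monitors it against exhaustive
enumeration (≥ 95 % of small random instances match, feasibility always
holds) and a pool-expansion cap of 10⁵ guards against pathological
livelock.

## Geometry engine

Per structure a linear BVH is built by sorting triangles on the 30-bit
Morton code of their **centroid**, quantised to 10 bits per axis over the
structure's inflated bounding box (x in the lowest interleaved bit), then
splitting each sorted run at the highest differing code bit until one
triangle per leaf; runs of identical codes split at the index midpoint.
Node boxes are exact triangle AABBs at leaves and child unions above.
Centroid quantisation is the standard choice for this construction; the
alternative (combining vertex codes) is ambiguous and was not used.

Segment-structure intersection is a stack traversal with slab tests and a
Möller–Trumbore segment-triangle test at leaves; an epsilon of 1e-9 on the
barycentric and parameter bounds makes touching (edge/vertex) contact count
as a hit, while exactly coplanar segments are treated as misses —
watertight arithmetic is deliberately not attempted.  Point-structure
distance is a best-first traversal ordered by box distance with the
pruning rule `f_bb < f_j`, exact region-based point-triangle distance at
leaves; it is exact to floating-point (verified against brute force to
1e-9 mm).  Inside/outside for the grey-matter surfaces is ray-crossing
parity along a fixed oblique direction `(1, 0.7, 0.3)/‖·‖`, retried along
up to two further fixed directions when a hit grazes an edge or vertex.
The traversal kernels are JIT-compiled (numba) over flat node arrays.

## Phantoms

The generator emulates the *topology and scale* of the clinical inputs
with one seeded random stream per scene: an icosphere skull (85 mm,
subdivision 4 → 2562 vertices) whose admissible template — a 150° polar
cap minus a 25° "face" patch — retains ~2300 entry vertices, inside the
2000–10000 range of real entry searches; vessels as capped parallel-
transport tubes (radius 0.5–2 mm) along smooth splines from the cortex
toward deep brain; sulci as open folded ribbons hanging 10–15 mm inward
from the pial sphere; grey matter as nested smoothly perturbed spheres
(70/55 mm, same perturbation field so the shell never pinches); and
targets drawn in the shell with ≥ 24 mm separation, re-drawn if their
entry-angle cone misses the admissible template (a real surgeon would not
pick an unreachable target either).  Phantom targets are shallower than
many clinical ones (trajectory lengths 20–40 mm vs. up to 80 mm), vessels
are far sparser than a real vascular tree, and no mesh carries
segmentation noise — passing tests therefore demonstrates algorithmic
correctness at clinical scale, not clinical performance.

The planted-conflict scene forces the contrast between independent and
joint planning: a spherical shield sheet (labelled a sulcus, so it blocks
without adding risk) leaves one 4 mm corridor shared by both targets —
any two trajectories through it sit closer than 8 mm, guaranteeing a
conflict — plus a second corridor for one target flanked by a vessel at
~6 mm so its risk lands one stratified bin higher.

## Numerical choices and sizes

* Vertex welding on load: round to 1e-6 mm, merge exact duplicates, drop
  degenerate and duplicate faces — idempotent, so a second save is
  byte-identical.
* Vertex normals: area-weighted incident-face average, outward enforced by
  signed volume for closed meshes; vertices without incident faces are
  flagged and excluded from entry candidacy.
* Hard constraints are strict inequalities; exact boundary values
  (length = 80 mm, angle = 25°, pairwise distance = 10 mm) are excluded,
  matching the constraint forms `<` and `> d_traj`.
* Test problem sizes — oracle sweeps on meshes ≤ 2000 faces with 1000
  queries each, planner cross-checks on 50 instances of ≤ 4 targets × ≤ 8
  candidates, order independence on five 4-target scenes, and one 8-target
  default phantom — were chosen as the smallest sizes that exercise every
  code path of the construction, traversal and search logic; all run on
  one CPU core in a few seconds.

## Known limitations

* No GPU traversal and no BVH refitting; hierarchies are rebuilt per scene
  (fast at phantom scale).
* The intersection epsilon convention means degenerate coplanar grazing
  contact can be missed; clinically irrelevant (a trajectory that close is
  rejected by the risk score) but formally non-watertight.
* `exhaustive_plan` is a test oracle, capped at 10⁶ combinations.
* Interactive re-planning with user-frozen electrodes is not a separate
  mechanism: truncating a target's candidate list to length 1 achieves it.
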