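# Methods

`polarflow` quantifies how blood flow organizes endothelial cell polarity
and vessel regression in a planar (retina-style) vascular plexus.  It runs
entirely on a spatial-graph representation of the vasculature and ships a
synthetic-retina generator with full ground truth, so every stage is
testable by planted-parameter recovery without microscopy data.

## The vessel network model

A `VesselNetwork` is an undirected spatial graph: nodes (branchpoints,
endpoints) carry 2-D positions in micrometres; segments carry a centerline
polyline, a per-vertex lumen radius profile (μm), a region label
(`artery`, `vein`, `capillary`, `sprouting_front`), a `lumen_fraction`
∈ [0, 1] (fraction of the centerline covered by patent, ICAM2-like lumen),
and a `has_matrix` flag (continuous Col.IV-like basement-membrane sleeve).
The plexus is treated as planar throughout: the developing superficial
retinal plexus is a quasi-2-D sheet, and every quantity consumed downstream
(per-segment shear magnitude, flow orientation, centerline geometry) is
well defined in 2-D.

## Haemodynamics

Flow is solved as a steady laminar Poiseuille network: each perfused
segment is a rigid tube of mean radius r and length L with hydraulic
conductance G = π r⁴ / (8 μ L); node pressures solve the Kirchhoff
conservation system with Dirichlet pressures at inlets/outlets; then
Q = G·ΔP, v = Q/(π r²), and wall shear stress τ = 4 μ |Q| / (π r³).
A full 3-D CFD treatment would add radial velocity profiles and
junction-flow detail that none of the downstream statistics consume —
the polarity and regression analyses use only the ordinal structure and
orientation of per-segment shear, which the 1-D model provides at a
fraction of the cost.

Numerical/physical choices:

* viscosity μ = 3.5·10⁻³ Pa·s, Newtonian and constant (no
  Fåhræus–Lindqvist haematocrit correction; a hook exists in
  `BoundaryConditions.viscosity`).  Absolute τ values are therefore on an
  arbitrary scale fixed by the boundary pressures; only comparisons across
  segments are meaningful, and all shipped statistics are ordinal or
  within-network.
* default boundary conditions: every arterial inlet at 60 Pa over venous
  outlets at 0 Pa.
* segments with `lumen_fraction` < 0.5 are excluded from the conductance
  matrix (non-perfused); blind-ended branches are stripped iteratively and
  carry Q = 0 exactly; connected components with no boundary node are set
  to outlet pressure with a warning.
* the sparse symmetric system is solved with a direct factorization;
  interior-node flow imbalance is < 10⁻⁸ relative to max |Q| (asserted in
  tests on thousands of segments).
* `classify_flow` labels segments below the 0.25 τ-quantile of perfused
  segments "low" (strictly below; ties and the all-equal case are "high");
  it refuses to classify fewer than 4 segments.

## Axial polarity

A cell's axial polarity is p = Golgi centroid − nucleus centroid (μm).
Against-flow polarization uses the angle θ ∈ [0°, 180°] between p and the
local flow direction, taken at the nearest centerline vertex of the cell's
segment so curved segments are handled.  Conventions:

* the against-flow window is the closed interval [135°, 180°]
  (the "180° ± 45°" window; 135° counts as against).
* the scalar product s = |p|·cos θ is signed (+ with flow, − against) and
  carries length units (μm); the sign-stratified OLS of s on τ therefore
  has gradient units μm/Pa.  Strata with < 3 cells or zero τ variance are
  skipped with a warning.
* cells with |p| = 0, unassigned cells, and cells on non-perfused segments
  have θ undefined and are excluded from angle statistics.
* nucleus↔Golgi pairing is greedy globally-nearest one-to-one matching
  with a 10 μm cap; cell→segment assignment is nearest-centerline with a
  15 μm cap, equidistant ties resolving to the lower segment id.
* group comparisons (low- vs high-shear, regression-adjacent vs distant;
  adjacency = nucleus within 20 μm of a profile centerline) use seeded
  two-sided permutation tests (median |p| difference, against-flow
  proportion difference) because no parametric form is assumed.

Against-flow percentages are reported both ways an across-retina figure
can be formed — pooling all cells, and averaging per-replicate fractions
(`against_flow_summary`) — since the two differ when replicates have
unequal cell counts.

## Regression profiles

A regression profile is an empty or emptying basement-membrane sleeve: a
matrix-positive segment whose lumen is deficient.  Detection and staging
(`detect_profiles`) use three config-exposed thresholds:

| threshold | default | meaning |
|---|---|---|
| continuity | 0.95 | lumen_fraction below ⇒ lumen deficient |
| disconnect | 0.50 | lumen_fraction below ⇒ retraction (stage 3) |
| stenosis ratio | 0.50 | min radius < ratio × median ⇒ focal dip |

A segment is a profile iff `has_matrix` ∧ (lumen_fraction < continuity ∨
stenosis dip).  Stages follow the four-step regression sequence; stage 1
("selection") precedes any morphological change and cannot be detected in
a static frame, so staging starts at 2: stage 4 (resolution) when
lumen_fraction = 0 with no resident cells; stage 3 (retraction) when
lumen_fraction < disconnect; stage 2 (stenosis) otherwise — i.e. lumen
largely continuous but focally dipped or marginally discontinuous.  The
rules are exhaustive and mutually exclusive, and the detector is monotone:
lowering any segment's lumen_fraction never removes a detection.

Resident cells are counted from the assigned cell table, excluding nuclei
that project within 4 μm of a segment endpoint: a nucleus sitting on a
shared branchpoint is ambiguous between the segments meeting there and
would otherwise contaminate genuinely cell-free sleeves.

Apoptosis colocalization uses a distance rule: a profile is positive when
any apoptotic event lies within 10 μm (one cell-body radius) of its
centerline.  With zero profiles the percentage is undefined (null), never
0.  Because the rule is distance-based, an event planted against one
profile occasionally also sits within 10 μm of an adjacent planted
profile, so recovered percentages run a few tenths of a point above the
planted rate — visible in the recovery tests and inherent to any
proximity-based colocalization measure.

The low-flow association (2×2 of profile status × shear class) must be
computed against flow solved on the *pre-regression* network — after
planting, regressed segments are unperfused by construction and the
association would be circular.  The odds ratio uses the Haldane–Anscombe
+0.5 correction when any cell is empty; the p-value is a seeded two-sided
permutation test on the profile labels.

## Radial profiling

All quantities are binned by distance from the optic center (default
100 μm bins): vascularized area (Σ L·2r over segment arc), nuclei,
branchpoints (degree ≥ 3 nodes), length-weighted mean τ over perfused arc,
and regression-profile counts.  Segments straddling a bin edge are
apportioned by arc length (2 μm arc steps), which makes bin merging
exactly additive.  Vascularized area comes from the graph so profiles work
on graph-only input; a raster-mask pixel-count alternative is available
(`vascularized_area(..., source="mask")`) and differs by junction overlap
and rasterization, typically a few percent.  Bins with zero area report
NaN densities.

## The synthetic retina generator

`netgen` emulates a whole P6 mouse retina at the scale the analyses need;
its defaults are the study conditions for all recovery tests:

* geometry: radius 1000 μm, 5 arteries and 5 veins alternating as radial
  spokes (tapering from 12/14 μm radius to capillary calibre), a jittered
  polar capillary lattice (40 μm spacing, angular resolution doubling
  outward, 12% random dropout of non-bridge radial links, radii
  3.2 μm × lognormal jitter), and blind sprouts on the outermost ring
  (the sprouting front).  Each artery terminates in exactly one inlet
  node and each vein in one outlet node at a small ostium radius (12 μm)
  from the optic center — distinct coincident nodes would fuse under
  rasterization and break mask→graph roundtrips.  Construction guarantees
  every non-sprout segment lies on an inlet→outlet path.
* cells: exactly 16,000 nuclei per retina, allocated over lumenized
  segments by one multinomial draw with weights ∝ length × residual lumen
  × a linear central density excess (factor 1 + g, default g = 1, toward
  the optic center).  Golgi are offset by |p| ~ N(5, 1.5²) μm (truncated
  at 0) at an angle to the local flow drawn von Mises(180°, κ); κ = 4 by
  default ("robust" polarization, ≈ 86% of cells in the against-flow
  window); κ = 0 is the uniform null.  Cells on unperfused segments draw
  uniform angles.
* regression: 5% of capillary segments, selected with probability ∝ 1/τ
  (low-flow biased, the physiological pattern; `regression_bias: none`
  gives the uniform null), staged 10/30/30/30% across stages 1–4.
  Stage 2 dips the central third of the radius profile to 0.35×; stage 3
  sets lumen_fraction ∈ (0.05, 0.45); stage 4 empties the lumen; the
  matrix sleeve always keeps its original calibre.
* apoptosis: Poisson(78.1) events per retina; round(4.82% × detectable
  planted profiles) events are placed on profile centerlines, the rest on
  the vasculature, rejection-sampled to stay > 11 μm from planted
  segments so the planted colocalization rate is exactly what recovery
  should measure.
* seeding: one master seed; fixed-offset substreams for network, cells,
  regression/apoptosis, so stages regenerate independently and identical
  configs give byte-identical outputs.

What the generator does **not** emulate: intensity noise and point-spread
blur (masks are binary), pericytes/macrophages, 3-D layering, true
honeycomb capillary topology (the lattice is quadrilateral-polar),
time-resolved dynamics, and Golgi fragmentation.  Passing recovery tests
therefore demonstrates that the measurement pipeline is unbiased and
correctly calibrated on clean planar geometry — not that it is robust to
segmentation noise in real microscopy.

## Mask rendering and extraction

Rendering draws per-vertex disks of local radius along centerlines into
binary channels (lumen, matrix, nuclei, golgi, caspase; default
1 μm/pixel) with a JSON channel manifest embedded in the TIFF.
Extraction skeletonizes the largest connected component (2-D thinning),
takes radii from the Euclidean distance transform, turns ≠2-neighbour
pixels into nodes and degree-2 pixel paths into segments, prunes spurs
< 5 μm, contracts branchpoint pairs closer than 6 μm (thinning splits an
X-crossing into two Y-nodes about one vessel radius apart), merges
degree-2 chains, and excludes 3 junction-adjacent samples per segment end
from mean radii (distance-transform radii inflate at branchpoints).  Path
tracing breaks ties in lexicographic pixel order, so extraction is
deterministic.  Annotation of lumen_fraction/has_matrix from masks
excludes vertices inside either endpoint's junction disk, where the lumen
of neighbouring vessels always overlaps the shared node.

On rendered synthetic plexuses, extraction recovers the generated topology
exactly (node counts by degree class, segment count) in ≥ 95% of runs with
mean-radius errors ≤ 1 pixel; residual failures are single stubborn
junction splits.

## Problem sizes used in the shipped tests

Recovery suites run on whole-retina defaults where the claim is about the
default conditions (colocalization, apoptosis count, cell count: 5, 8 and
1 replicates respectively) and on reduced plexuses (radius 280–400 μm)
for property suites, calibration (200 null replicates, 400-permutation
tests) and roundtrips, keeping the full suite within a few minutes on one
CPU.  Sizes are fixtures of the tests, not limits of the code: the flow
solver factorizes the default ~3,700-segment plexus in well under a
second, and the acceptance script regenerates everything from scratch at
the default scale.

## Known limitations

* Absolute pressures/velocities/shear are not calibrated to physiology;
  only within-network comparisons are meaningful.
* Nearest-segment assignment misattributes a few percent of
  junction-adjacent cells; against-flow fractions measured through the
  full pipeline are attenuated by roughly the misassignment rate times
  the contrast to uniform.  The statistics layer is validated against
  closed forms using ground-truth assignment.
* Stage-1 ("selection") regression is a generator concept only; no static
  morphology distinguishes it.
* The 2-D model cannot represent the deeper retinal plexuses or
  out-of-plane polarity components.
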