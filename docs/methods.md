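# Methods

This note documents the model behind `dgforest`, its assumptions, the
parameters that matter, the numerical choices, and what the packaged
tests do and do not demonstrate.

## The layered volume

The dentate gyrus is modelled as five offset shells of one parametric
surface family. A point is addressed by three coordinates:

* `v` ∈ (−0.23π, 1.425π) sweeps the "C"-shaped transverse
  cross-section (an ellipse arc; the gap in the arc is the hilar
  opening);
* `u` sweeps the septotemporal axis (0.01π–0.98π for the GCL shells,
  −0.016π–1.01π for the ML shells, so the ML caps the GCL ends);
* `L` indexes the shells: −1.95 (inner GCL), 0 (outer GCL), 1 (IML),
  2 (MML), 3 (OML). `L` is affine in the normal offset, with separate
  µm-per-unit scales for the GCL (`w_gcl` ≈ 80.7 µm) and the ML
  (`w_ml` ≈ 86.2 µm).

The surface is a cut elliptical torus: the cross-section semi-axes are
scaled along `u` (end taper with a septal/temporal size asymmetry), the
cross-section aspect ratio varies from tall/narrow septally ("V"-shaped
sections) to flat/round temporally ("U"-shaped), and the center curve
carries a smooth z-deflection. Layer offsets add to both cross-section
semi-axes, which makes the family **analytically invertible**: a point
is classified by solving one monotone scalar equation for its shell
offset (vectorized bisection), rather than by distance queries against
triangulated meshes. Classification of ~10⁷ points per second is what
makes full-GCL packing and 10⁷-sample Monte-Carlo volumes cheap.

Free coefficients (global scale, shell spacings) were fitted by a
fixed-point loop (`scripts/calibrate_geometry.py`) to three anatomical
constraints — GCL volume 3.78 mm³, ML volume 9.02 mm³, mean ML width
247 µm — and the cross-section shape ratios were chosen so that (a)
septal sections are sharper-crested than temporal ones and (b) the
GCL→ML area growth supports the published packed-soma count. The
calibrated model reproduces all three constraints to well under 1%,
and packs 1,195,789 somata (+0.9% vs the reference population count).
The model's ML-width spread (sd ≈ 13 µm) is tighter than the
atlas-derived reference (±33 µm) because the parametric surfaces are
smoother than reconstructed anatomy; only the mean is calibrated.

Sublayer volumes under this calibration are IML 2.65, MML 3.03,
OML 3.36 mm³ (the shells grow outward on the convex side). These
numbers matter for the laminar density gradient below.

## Soma packing

Close-packed hexagonal layers (ABC stacking, nearest-neighbour spacing
12.54 + 3.5 µm) aligned to the bounding box with a seeded random
phase; spheres are kept only if they fit entirely inside the GCL
(normal distance to both GCL shells ≥ one radius, evaluated from the
shell-offset coordinate and the local offset-to-normal rate). Blade
labels split the population at the midpoint of `v` (ties to
suprapyramidal), depth labels at normalized GCL depth 0.5 (superficial
= the half nearest the ML). The calibrated geometry yields 30.4%
supra-superficial, 26.2% supra-deep, 23.0% infra-superficial, 20.4%
infra-deep.

## Tree growth

**Wiring.** Targets are attached greedily; the cost of attaching
target `t` to node `n` is `‖t−n‖ + bf·(plen(n) + ‖t−n‖)`, i.e. the
increment of *total cable + bf × summed path length* — the greedy
step on the dual wiring objective. With this form `bf = 0` is exactly
Prim's MST, and balancing factors above 1 (the printed granule-cell
values reach 1.35) remain meaningful. The naive alternative
`‖t−n‖ + bf·plen(n)` degenerates to a star topology for every
`bf ≥ 1` (attaching near the root is then always optimal), which is
incompatible with granule cells' observed branch orders; this package
therefore uses the incremental-objective form throughout. Ties resolve
to the lowest target index.

**Stems.** A truncated-Poisson count on {1..4} (rate solved so the
mean matches the subgroup value: 2.4 supra-superficial, 1.5
supra-deep/infra-deep, 1.9 infra-superficial — the infrapyramidal
means are not individually published and were chosen so the
blade-weighted mixture reproduces the overall 1.8). Stem seed points
are sampled in the cone opening 10 µm above the soma and force-attached
to the root, which then accepts no further children, so root degree
equals the stem count by construction.

**Dendritic fields.** Each cone points from the soma to the nearest of
2×10⁶ OML-boundary points; the transverse semi-axis (along the local
`v` tangent) exceeds the longitudinal one (`radius_ratio` ≈ 0.54–0.62).
Per-cell radii are normal draws truncated at zero.

**Laminar target quotas.** Per-cell Poisson draws around calibrated
per-layer means (GCL ≈ 1.3, IML ≈ 18–22, MML ≈ 6–7, OML ≈ 16–18
depending on subgroup). Two structural parameters shape where targets
sit *within* layers: a per-layer radial exponent (proximal GCL/IML
targets cluster near the trunks, distal MML/OML targets crowd the
periphery of the fan) and an OML depth band ((0.85, 1.0): OML targets
lie in the outer 15% of the shell, so terminal branches cross the full
molecular layer). These stand in for the unpublished empirical
branch/termination-point distributions and were calibrated, together
with the quotas and radii, against the published laminar and subgroup
tables (`scripts/calibrate_growth.py` plus a documented manual
refinement).

**Resampling.** Branch-wise even re-spacing at ~5 µm (segment count
`round(length/5)`), preserving branch and termination points exactly.
Resampling is quasi-idempotent: corner-cutting can shift a branch's
segment count by one when its length sits at a rounding boundary.

**Jitter.** A stationary Gaussian displacement field with
squared-exponential correlation, realized by random Fourier features
at two length constants (10 and 50 µm; per-axis amplitudes 3.5 and
15 µm), evaluated at the node positions. A single smooth spatial field
(rather than independent per-branch noise) keeps branch points
attached to their branches with no seams; the root is pinned.
Amplitudes are calibrated so the population mean contraction
(branch-wise Euclidean/path ratio) sits near 0.87, inside the 0.85–0.95
band of real reconstructions.

**Confinement.** Jitter can push boundary-hugging nodes out of the
shell stack. Displaced nodes are projected back to 1 µm inside the
violated boundary (shell offset clamped; the open arc of the "C" and
the septotemporal ends are clamped likewise), the way real granule-cell
dendrites are physically bounded by the hippocampal fissure and the
hilar border. After confinement every node classifies inside the
volume.

**Taper.** `d(x) = [d_tip + (d_max − d_tip)(1 − x/X)²] · min(1,
expm1(x/λ))` with `x` the path distance, `X` the cell's maximal path
length, `d_tip` 0.65 µm, per-cell `d_max` ~ N(2.2, 0.35) µm and
λ = 4 µm. The `expm1` ramp suppresses the taper only within the first
~3 µm of the soma; how the published near-soma scaling combines with
the quadratic term is ambiguous, so the multiplicative normalized form
was fixed and exposed in the config. At the 5 µm sampling interval the
ramp saturates within the first segment; a final pass lifts any
jitter-induced proximal undercut to its subtree maximum so diameters
are non-increasing from soma to tip. Diameters are floored at 0.3 µm,
and the root keeps the 12.54 µm soma diameter.

**Determinism.** Every cell draws from an independent substream keyed
by `(master_seed, cell_id)`, so populations are order-independent and
a cell can be regenerated alone, byte-identically.

## Morphometrics conventions

* Branches are paths between topological points (root, branch points,
  tips); branch order counts branch points on the path from the root.
* Partition asymmetry: mean over bifurcations of `|l−r|/(l+r−2)` for
  child subtree tip counts, degree-2 partitions contributing 0. Under
  this convention a finite comb with n tips scores `(n−2)/(n−1)`
  (approaching 1), and a full binary tree 0. Higher-order branch
  points (a by-product of greedy wiring, excluded because the measure
  is defined for binary partitions) fall back to a child-pair mean
  only when a tree has no bifurcations at all.
* Spreads: terminal tips are projected into an orthonormalized local
  surface-tangent basis at the soma; the transverse spread is the tip
  extent along the principal in-plane direction (re-labelled so
  "transverse" stays closest to the `v` tangent), the longitudinal
  spread the extent along the in-plane orthogonal.
* Laminar distributions attribute each segment to the layer of its
  midpoint, with GCL folded into IML (the reference tables' convention).
* `se_to_sd` converts reported standard errors with the conventional
  `se·√n` by default; the verbatim literature conversion (`se·n`) is
  available as `convention="stated"`.

## Population analyses

Occupancy grids bin 5 µm segment centers into 25 µm cubes (unique cell
count, summed length, cable density, percent cylinder volume). Two
statistics deserve care at less-than-full population density:

* Means over *occupied* cubes underestimate density in large sparsely
  covered layers, so the laminar gradient is evaluated in the dense
  limit (`laminar_cable_density`: layer cable over layer volume —
  the mean over all cubes including empty ones). On calibrated
  populations cable density rises from IML to OML while volumetric
  occupancy falls (the taper thins distal cable); the profile through
  the MML is not monotone — the published laminar length shares
  (29/32/39%) against these sublayer volumes imply the same dip.
* Cube-level correlations between the three occupancy measures are
  meaningful only where dendrites genuinely overlap, so they are
  evaluated on region-restricted populations (all cells drawn from a
  thin septotemporal window).

Axon complexity wires random points in a cube at `bf = 0` (an MST),
starting from 2 points and adding 5 at a time until the 1 µm-resampled
axon passes within 5 µm of every cell present, averaging branch-point
counts over 10 independent collections. Starting at 2 points keeps the
single-cell case branchless (a 3-node wiring is always a path).
Surface maps average per-cell statistics over the nearest of 5000
triangular faces of a GCL shell.

## Scaled-down operating points

The full forest (1.19 M cells) is cluster-scale; the packaged tests and
the acceptance script use desk-scale sizes chosen as the smallest runs
that estimate each quantity stably: 10⁶–10⁷ Monte-Carlo samples for
volumes, the full soma packing (it takes seconds), 200 mixed cells for
population tables (mean standard errors a few percent of the reference
sds), 100 cells for the stem-count statistic, and 150-cell
septotemporal-window populations for overlap analyses. Cluster-scale
quantities that require the complete forest (hundreds of unique cells
per 25 µm cube and the corresponding axon complexities) are not
reproduced at desk scale; the package computes the same measures on
local populations where the qualitative structure (positive
correlations, laminar gradients) is already present.

## Known limitations

* Total dendritic length calibrates to ~2750–2850 µm against the
  published 3357 µm (−15%): with the ML width and layer volumes pinned
  exactly and branch counts matched, path lengths are bounded by the
  247 µm ML traverse, and the residual is the price of those exact
  geometric constraints. Transverse spreads correspondingly run
  ~15–25% above the published subgroup values (the cones widen to
  carry cable), though their subgroup ordering and contrasts are
  preserved.
* The parametric shells are smoother than real anatomy (narrower ML
  width distribution; no local curvature noise).
* Multiple dendrites may occupy the same space (no dendro-dendritic
  avoidance), somata are spheres rather than packed ellipsoids, and
  newborn GCs with basal dendrites are not modelled.
* Passing tests demonstrate consistency with the published summary
  statistics of the reference reconstructions, not equivalence with
  any individual real cell; the generator's variability is calibrated,
  not learned from reconstruction-level data.
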