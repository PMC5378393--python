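# Methods

`trabmorph` quantifies trabecular (cancellous) bone micro-architecture from
isotropic 3D micro-CT volumes, following the cylindrical-rod view of the
trabecular network: the bone compartment is decomposed into *segments* (rods
with a length and a radius) meeting at *connecting nodes* (junctions where
three or more segments join). Around that core it provides the standard
global morphometric parameters, phantom-calibrated densitometry, and the
two-group statistical layer of a diet-intervention study. All stages are
exercised against synthetic phantoms with exact generative ground truth.

## Geometry conventions

Volumes are `(z, y, x)` arrays with an isotropic voxel size in mm; voxel
centers sit at `(i + 0.5) * voxel_size`. Slab intervals (ROI extraction) are
half-open. Foreground and skeleton connectivity is 26; background is 6. The
working resolution throughout the synthetic study design is 9 µm, the
resolution class of small-animal desktop micro-CT.

## Region of interest

The metaphyseal ROI is referenced to the growth plate, supplied as a plane
index (automatic growth-plate detection is out of scope; on synthetic data
the reference is plane 0). The slab starts `offset` mm past the reference
(default 0.5 mm) and spans `extent` mm (default 2.0 mm); at 9 µm this is a
222-plane slab starting 56 planes past the reference. The total tissue
volume (TV) is the full slab — bone and marrow alike — which is also the
denominator of BMD and of the segment/node densities.

## Binarization

Default is Otsu's threshold on a 256-bin histogram of the ROI; a fixed
threshold is available when an acquisition-specific value is known.
Foreground is `intensity >= threshold`, making the mask monotone in the
threshold. A constant-intensity ROI is an error, not an empty mask.

## Global morphometry

* **TV, BV, BV/TV** — direct voxel counting times the voxel volume.
* **Surface area** — marching-cubes triangulation of the bone interface.
  The scalar field is the signed Euclidean distance transform, shifted by
  half a voxel so level 0 is the bone/background interface and smoothed with
  a small Gaussian (sigma = 0.6 voxel) to suppress lattice quantization;
  meshing the raw binary field instead overestimates a smooth surface by
  ~8 % (staircase bias), while this construction is within 1 % of the
  analytic sphere area at r = 20 voxels. An exposed-voxel-face count is
  retained as an exact combinatorial diagnostic (it overestimates smooth
  surfaces by a known bounded factor, 1.5 for a sphere).
* **SA/V** — mesh surface area over BV.
* **Structure model index (SMI)** — the differential-surface definition
  `SMI = 6 V S' / S^2`, where `S'` is the derivative of surface area under an
  outward offset of the iso-surface. The offset is implemented by displacing
  mesh vertices along their (outward-oriented) normals by half a voxel and
  taking a central difference; no re-meshing is involved, which removes the
  curvature bias of meshing an offset level set. Convex reference solids
  give the textbook limits: long cylinder 3, thin plate 0, sphere 4 (the
  digitized cylinder of finite length L and radius r has the exact value
  `3L(L + pi r)/(L + r)^2`, ~3.15 at L = 20 r). Concave structures can
  legitimately leave [0, 3]; no clamping is applied.
* **Fractal dimension** — volume-occupancy box counting: occupied boxes of a
  grid-aligned partition at sizes 2, 4, 8, … (at least four sizes spanning
  two octaves), FD = −slope of the unweighted least-squares fit of
  log(count) against log(size). The partition is anchored at the foreground
  bounding box, making the estimate translation invariant; a solid cube then
  reads exactly 3.0 and an isolated plane exactly 2.0.
* **Vertical length** — distance in mm from the reference plane to the
  farthest plane containing at least one bone voxel on the metaphysis side;
  "no bone past the reference" returns 0 with a warning flag rather than an
  error.

## Densitometry

The calibration phantom is a cylindrical epoxy body carrying hydroxyapatite
inserts of known density (the standard 5-step 200–1000 mg-HA/cm³ ladder).
Calibration fits ordinary least squares with density as the response —
insert densities are manufactured ground truth, the per-insert mean
grayscales carry the noise — giving `density = slope * gray + intercept`
with r². Per-voxel calibrated densities are clamped below at 0 (the
sub-water range is not meaningful for mineral density). BMD is the mean
calibrated density over *all* TV voxels; a bone-restricted tissue mineral
density is reported as a secondary output. BMC = BMD × TV, which with BMD
in mg-HA/cm³ and TV in mm³ is in micrograms of hydroxyapatite; BMC is
reported in µg-HA throughout (the published table this mirrors labels the
column mg-HA, but its printed values equal BMD × TV only on the microgram
reading — the unit is documented rather than silently reproduced).

## Rod-graph extraction

1. **Distance map** — exact Euclidean distance transform of the mask,
   scaled to mm (a single foreground voxel reads one voxel size:
   center-to-nearest-background-center convention).
2. **Skeletonization** — topology-preserving 3D medial-axis thinning
   (Lee's algorithm) to a one-voxel-wide, 26-connected skeleton.
3. **Graph building** — skeleton voxels are classified by 26-neighbor count
   (1 endpoint, 2 path, ≥3 junction); 26-adjacent junction voxels merge into
   one connecting node at their centroid, which also records the local
   distance-field value as the *joint ball radius*. Voxel chains between
   nodes become segments. Closed loops with no junction are kept as a
   single self-loop segment anchored at an arbitrary loop voxel, so cycles
   survive.
4. **Segment length** — the voxel path (with node centroids appended) is
   smoothed by a centered moving average (window 7, endpoints pinned) and
   its polyline length taken. Raw face/edge/corner step sums overestimate
   oblique digital lines by up to ~10 %, far outside the 2 % accuracy this
   pipeline targets; the smoothed polyline is orientation-robust. At free
   (endpoint) ends, thinning stops short of the true rod end inside the
   cap; the length is extended by marching along the local tangent of the
   smoothed centerline to the interpolated bone boundary and subtracting the
   local distance-field value plus a quarter-voxel digitization offset.
   Across rod orientations and radii 3–10 voxels this recovers isolated rod
   lengths within ~1.5 %.
5. **Segment radius** — mean distance-field value over the segment's path
   voxels, the local maximal-ball radius, exact for cylindrical rods. For
   isolated digitized rods of radius 3–10 voxels the error stays within
   0.6 voxel.
6. **Pruning** — three artifact-removal rules iterated to a fixed point:
   spur removal (endpoint-terminated segments shorter than `min_length`,
   default two voxels, or shorter than `joint_scale` — default 2 — times the
   radius of the joint they hang from); joint contraction (junction-junction
   segments shorter than `joint_scale` times the local joint-ball radius are
   collapsed, merging the split skeleton clusters that thick multi-rod
   joints produce); and dissolution of junctions *reduced* to degree 2 by
   the previous rules (their two segments merge, lengths added, radii
   length-weighted). Pre-existing degree-2 nodes are left alone, so pruning
   a clean graph is the identity and pruning is idempotent. The joint
   contraction threshold is deliberately tied to the measured joint ball
   rather than a fixed length: the lateral extent of joint splitting scales
   with rod radius over the sine of the inter-rod angle.
7. **Statistics** — segment/node counts and densities (per TV), unweighted
   mean length and radius, total trabecular length. The connecting-node
   count includes junctions only (degree ≥ 3); endpoints are tracked but not
   counted as nodes.

Distributions of segment length and radius are fixed-width unnormalized
histograms (the counts sum to the segment number); default bin widths are
0.0055 mm for length and 0.00275 mm for radius, the natural granularity of
radius estimates at 9 µm voxels. Local maxima are detected on a moving-
average-smoothed histogram (window 3 bins): a bin (or plateau center) whose
smoothed count strictly exceeds both flanks; the global maximum is flagged.
The positions of radius-histogram maxima at this resolution largely reflect
distance-field quantization, and the package attaches no biological reading
to them.

## Group statistics

Per group: mean, SEM (n−1 standard deviation over √n) and CV (%). The
two-group comparison first applies a two-sided variance-ratio (F) test at
the same alpha — reports label this column "z test", the term used in the
source study's methods for its equal-variance screen, which is not a
standard named procedure — then a pooled-variance t-test if equality is not
rejected, otherwise Welch's test; all tests two-sided, alpha
0.05, no multiple-testing correction (each parameter at raw alpha, matching
the study design being mirrored). Percent change is
`100 * (basal − low)/basal`, positive meaning a decrease; values are kept at
full precision internally and rounded only at report time, half-up, two
decimals for morphometric and zero for biochemical variables. Degenerate
zero-variance comparisons return p = 1 (equal means) with an explicit flag.

## Synthetic phantoms

The rod-network generator builds a *geometrically realizable* truth graph
and rasterizes it:

* Junctions are placed by growth: each new junction sits at an
  exactly-drawn rod length (from `length_dist`) in a random direction from
  a random existing junction, subject to a minimum junction separation
  (0.45 × mean length), an inter-rod angle of at least 55° at shared
  joints, a two-voxel surface clearance between disjoint rods, and
  clearance from foreign joint balls. Pendant rods (free ends) then bring
  every junction to degree ≥ 3 and fill the segment budget
  `round(n_nodes * mean_degree / 2)`.
* Every rod keeps its drawn length while hunting for a feasible placement;
  lengths are never resampled on failure, because resampling couples the
  realized length distribution to crowding and hence to the group's rod
  budget — exactly the confound the two-group design must exclude.
* Rods are rasterized as capsules (hemispherical caps keep joints
  connected); a voxel is foreground iff its center lies inside a capsule;
  overlaps are unioned. Grayscale is a mineral-intensity foreground level
  plus additive Gaussian noise (the detector noise of the emulated
  instrument is uncharacterized; an unbiased perturbation is all the
  calibration and thresholding stages require).

The two-group generator programs the low-Mg phenotype: the junction budget
scales by `segment_count_ratio` (default 0.7) and the mineral intensity by
`density_ratio` (default 0.85), while the length/radius distributions are
shared (scaled by `1 − length_radius_shift`, default shift 0). Between-
animal variation is 10 % CV on the junction budget and 3 % on intensity —
a deliberately well-powered design for n = 8 per group. Per-animal seeds
derive from the study seed through `numpy` seed sequences, so a study is
bitwise reproducible. The default per-animal ROI is a 120³ box at 9 µm
with ~45 rods of mean length 0.27 mm and mean radius 0.032 mm; the box is
sized so that placement failures are rare in *both* groups, which keeps the
realized length distribution identical across densities (in a tighter box,
long rods fail to place more often in the denser basal group, biasing its
mean length low by 1–2 %).

What the phantoms do not emulate: plate-like and mixed-morphology
trabeculae (beyond the analytic test solids), partial-volume blur and
beam-hardening/ring artifacts, cortical bone and the growth plate itself,
spatial gradients in trabecular density, and anatomically realistic network
topology (the truth graph is a grown tree plus pendants, not a remodelled
lattice). Passing the recovery and study-level tests therefore demonstrates
the correctness of the measurement chain on rod-like structures with known
truth, not instrument-level fidelity on real scans.

## Problem sizes and simulation design

Unit and example tests run on small digitized solids (≤ 170³ voxels).
Graph-recovery validation uses networks of ~50 rods on 20 junctions with
radii 3–10 voxels in a 170³ box, where counts recover within 10 % of truth.
Study-level validation uses 25 replicate 8-vs-8 studies at the default
120³ per-animal ROI for power (segment count, node count and BMD all reach
100 % detection at the programmed effect; mean length/radius stay below a
10 % false-flag rate), and 200 reduced-size truth-level studies
(4 vs 4 animals, 12-junction networks) for the type-I error, which lands at
the nominal 5 % within binomial error. These sizes were chosen so the full
validation cycle completes in minutes on a single core while keeping every
statistical check adequately replicated.

## Numerical choices and degenerate inputs

* Histogram bins start at the floor of the data in bin-width units and are
  half-open, with the last edge strictly past the maximum (no value drops).
* Otsu on a constant image, empty TV regions, all-foreground distance maps,
  empty histograms and sub-minimal group sizes raise errors; empty masks
  skeletonize to empty skeletons and empty graphs summarize to zeros with a
  warning record (a legitimate "no bone" observation).
* Non-thin skeletons passed to the graph builder are rejected with the
  offending voxel coordinate.
* Calibration requires at least two distinct gray levels; two points yield
  the interpolating line with r² = 1.

## Known limitations

* Radius estimates inherit distance-field quantization (~±0.3 voxel) and a
  mild negative bias near rod ends; sub-voxel radii are not resolvable.
* Junction positions are skeleton-cluster centroids and can sit 1–3 voxels
  from the geometric rod intersection for thick, shallow-angle joints; the
  induced per-segment length error grows for segments much shorter than
  the joint ball.
* SMI and mesh surface area are not exactly invariant under axis
  permutation (marching-cubes triangulations are orientation-dependent at
  the ~1 % level).
* The variance-gated test choice mirrors the emulated study's procedure; it
  is not the recommendation of modern practice (which would default to
  Welch), and no multiplicity correction is applied by design.
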