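# Methods

This note documents the models, conventions and parameter choices behind
`vasculonet`, and what the phantom-based validation does and does not
establish.

## Coordinate and unit conventions

Volumes are arrays indexed `(i, j, k)` = (x, y, z), z being the TIFF page
index. The world coordinate of the center of voxel `(i, j, k)` is
`origin + voxel_size · (i, j, k)`; all physical quantities are in μm
(lengths), cm (total network length) and mm³ (volumes). Only isotropic
voxels are supported — the target imaging regime is 2 μm isotropic — and
all indices are 0-based. Keeping one convention everywhere removes a
whole class of off-by-one and unit errors between modules.

## Segmentation

**Local thresholding.** A voxel is foreground when its intensity exceeds
the mean over a cubic window of half-width `window_radius` (default 25
voxels ≈ 50 μm) plus `offset` (default 10). The window must exceed the
width of the widest vessel so that the local mean estimates background
rather than vessel interior; 50 μm clears most vessels at the target
scale. The window mean (not a median or Otsu split) keeps the operator
separable and cheap on large volumes, and truncates at volume borders
(the mean is over the voxels actually present).

**Insideness gap filling.** Intraluminal staining labels vessel walls and
leaves the lumen dark, with gaps where stain is missing. The filling
operator defines the *insideness* of a voxel as the fraction of a fixed,
deterministic set of ray directions along which vessel material is hit
within `max_radius`. Background voxels at or above `inside_fraction` are
converted; the operator iterates to a fixpoint (converted voxels support
further conversions) with a hard cap of 10 passes. It is extensive and
monotone by construction.

Two operating points matter:

* *default* (`n_rays=26` neighbour directions, `inside_fraction=0.85`,
  `max_radius=45` μm — just above the largest vessel radius expected in
  the data): conservative; fills enclosed lumina and never grows open
  surfaces. On sealed hollow phantoms it reaches its fixpoint in ≤ 3
  passes.
* *gap closing* (`GAP_FILL_PARAMS`: `n_rays=66` Fibonacci directions,
  `inside_fraction=0.60`, `max_radius=20` μm): closes punctures through
  the wall. A voxel in a wall hole sees the filled lumen below and the
  hole rim around it, giving insideness distinctly above the ≈ 0.5 of a
  background voxel resting on an intact surface, so holes close
  progressively from the rim inward while open surfaces do not dilate.
  The threshold sits between those two regimes; the finer direction set
  is needed to resolve the difference on curved walls. At this operating
  point the 10-pass cap also bounds a slow residual creep at concave
  junctions, which is included in the measured spurious-voxel rates.

**Largest component.** Connected-component labelling (6/18/26
connectivity, default 26) keeps the largest component; ties break to the
component containing the lexicographically smallest voxel so results are
reproducible.

## Skeletonisation, radii, tracing

Skeletonisation uses 3D topology-preserving thinning (Lee's method via
scikit-image), which preserves foreground 26-connectivity and background
6-connectivity; correctness is asserted through topology-preservation
tests (components and independent cycles) rather than voxel-exact
agreement with any particular thinning implementation.

The radius at a skeleton voxel is the Euclidean distance to the nearest
off voxel. Because the nearest off voxel to an interior point is always
6-adjacent to the surface, the query runs against boundary voxels only (a
KD-tree), which is much cheaper than a full distance transform on large
volumes and numerically identical.

Tracing classifies skeleton voxels by their number of skeleton
neighbours: junction voxels (≥ 3) cluster with adjacent junction voxels
and collapse to a node at the cluster centroid; endpoints (1 neighbour)
are nodes; maximal chains of 2-neighbour voxels become segments; an
isolated simple cycle receives one anchor node (its lexicographically
smallest voxel) and a self-loop segment. The graph is a multigraph:
self-loops and parallel segments are legal, since real capillary beds
contain reconnecting arcades.

Three corrections address known thinning artifacts, in this order
(`extract_topology`):

1. **Junction collapse.** Thinning a thick vessel can split one branch
   point into nearby junction groups joined by very short chains, or
   leave a tiny triangle/ladder loop. Internal segments joining two
   junctions are contracted, and short self-loops deleted, when shorter
   than the larger of a fixed floor (default 15 μm) and twice the local
   end-point radius — these artifacts scale with the vessel radius.
   Shortest links are contracted first because contracting one rung of a
   ladder lengthens its partners.
2. **Spur pruning.** Terminal segments shorter than `min_length`
   (default 15 μm) or thinner than `min_mean_diameter` are removed and
   the two segments across any resulting degree-2 node merged, repeated
   to a fixpoint. Pruning never splits a component. Pruning runs before
   tip extension so spurs are judged by their raw length.
3. **Tip extension.** Thinning erodes rounded vessel ends; each terminal
   segment is prolonged along its end direction to the point one
   tip-radius short of where that ray exits the mask, which restores the
   eroded portion without overshooting.

Segment polylines receive two Laplacian smoothing passes (interior points
only) to remove voxel-chain staircase jaggedness, which otherwise
inflates length measurements by several percent.

**Derived per-segment quantities.** Length is the polyline arc length.
Diameter is the length-weighted mean of the per-point diameters; when a
segment has at least 4 points its first and last point are excluded,
because the distance-transform radius is inflated inside junction blobs.
Volume is the sum of conical frusta between consecutive points. One
diameter convention had to be fixed where several are defensible; the
weighted-mean-with-junction-exclusion choice is validated against
phantoms only.

## Analytics

* **Branch counts** are BFS edge distances from a user-chosen source node
  (in real data the feed artery or vein, identified by inspection;
  `suggest_feeders` proposes the widest degree-1 nodes). Edge count was
  chosen over junction count for the ambiguous notion of "branches along
  a path" because a first-generation branch off the feeder then has
  count 1. Parallel segments count once; unreachable nodes are flagged,
  never reported as 0.
* **Diameter-window subnetworks.** `select_by_diameter` keeps segments by
  diameter window and minimum length plus an explicit exclusion list (the
  stand-in for manual removal of known arterial branches). The pHEV
  preset is 16–32 μm and ≥ 40 μm. `split_trees` (> 15 μm, two largest
  components) separates candidate arterial/venous trees; no flow
  direction is inferred.
* **Organ region.** Morphological closing of the vessel mask with a
  Euclidean ball (default 60 μm) plus hole filling. The closing is
  computed with two distance transforms, which is exact and affordable at
  large radii.
* **Distance fields.** The region is overlaid with a grid (default
  4 μm); for every grid point inside the region and outside vessels the
  distance to the nearest vessel *voxel center* is computed (at 2 μm
  voxels the difference from surface distance is sub-voxel; the
  brute-force test oracle uses the same convention). When the grid is
  voxel-aligned this samples a distance transform, otherwise a KD-tree;
  both agree exactly with the brute-force scan. Voids are grid points
  farther than a threshold (default 60 μm), exportable as a 0/255 TIFF
  at grid resolution.
* **2D histology.** A crossing is recorded where a centerline polyline
  changes side of the plane (runs of points exactly on the plane count
  once); the local diameter is linearly interpolated. Density divides
  crossings by the region's cross-section area, and only crossings whose
  in-plane position falls inside the region slice are counted — counting
  outside crossings would make the density inconsistent with its
  denominator.
* **Subregion statistics** use world-coordinate blocks; 3D density counts
  segments whose arc-length midpoint lies in the block (midpoints
  partition space, so block counts are additive), and 2D density comes
  from the histology rule on the block's central z-plane.
* **Benchmark ratio report.** `table_ratio_report` computes subnetwork /
  whole-network percentage cells at reporting precision (integer percent
  for counts, diameters and volume; one decimal for the length fraction;
  two decimals for organ-volume fractions). `validation.py` carries the
  published whole-LN and pHEV totals of a murine lymph-node network as
  inputs for this arithmetic; the original image volume is not publicly
  deposited, so absolute statistics cannot be re-derived from data and
  the pipeline is validated on phantoms instead.

## Phantoms and what the validation shows

`generate_tree` builds seeded binary trees: per generation the radius
shrinks by `radius_ratio`, segment lengths and branch angles are drawn
uniformly from configured ranges, the two children leave in roughly
opposite azimuths, and geometry that would leave the domain or violate
the optional `min_separation` (surface-to-surface gap between
non-adjacent segments) is re-sampled with fresh branch angles —
re-rolling rather than bending keeps the branch-angle statistics intact
and keeps siblings at least twice the minimum branch angle apart. The
generator is pure: identical spec, identical tree.

Rasterisation marks voxels whose centers lie within the segment radius of
the centerline (solid: a capsule union) or within the wall shell
`[radius − wall, radius]` (hollow), then deletes a seeded fraction of
wall voxels in contiguous spherical patches (default patch radius 4 μm) —
contiguous holes, not salt-and-pepper noise, because holes through the
wall are the failure mode the insideness filler must close.

Validation presets (the conditions under which the pipeline's accuracy
claims are measured):

* `recovery_spec` — solid trees of depth 4–6 at 2 μm voxels; radii
  10 → 4.4 μm (all ≥ 2 voxels), segment lengths 45–80 μm, branch angles
  25–55°, 20 μm (10-voxel) guaranteed branch separation. Across batches
  of 20 phantoms the tracer recovers the exact segment count and
  node-degree multiset in ≥ 19/20, with ≥ 99% of segment diameters
  within one voxel and ≈ 99% of lengths within 10%.
* `hollow_spec` — hollow arteriole/venule-scale trees (radii ≈ 10–20 μm,
  4 μm wall, 10% gaps) with wall signal 200 on background 10 plus
  Gaussian noise (σ = 3). The pipeline recovers ≥ 99% of the true solid
  voxels with ≤ 5% spurious additions and a single connected component.
  Capillary-scale walls (lumen ≲ 1 voxel) are below the gap-filler's
  working range: holes in strongly curved thin walls cannot be separated
  from open surface by the insideness statistic; their residue is a
  one-voxel surface dent.

The phantoms emulate tube geometry, tapering, branching density, wall
staining and gaps, and imaging noise. They do **not** emulate loops
(arcades) in the generator — the tracer handles cycles, tested on
hand-built looped masks and tori —, nor intensity heterogeneity along
vessels, shrinkage, anisotropic PSFs or touching adjacent vessels.
Passing the phantom batteries therefore demonstrates correctness of the
geometric/topological machinery under clean tube geometry, not
performance on any particular instrument's data.

## Numerical choices and degenerate inputs

Ties in component selection and cycle anchoring break lexicographically.
Writers emit fixed 4-decimal ASCII, so identical networks produce
byte-identical files; SpatialGraph "thickness" stores the radius. An
empty mask skeletonises to an empty skeleton; an empty network summarises
to zeros; an empty vessel mask makes the distance field undefined and
raises. Histology planes outside the volume, unknown branch-count
sources, inconsistent mask geometries and invalid phantom specs raise
immediately with specific messages.

## Problem sizes used in the shipped validation

The test suite and acceptance script run phantoms in domains of
700–1000 μm per side at 2 μm voxels (350³–500³ arrays), 20 phantoms for
topology recovery and 2 hollow phantoms for gap closing; brute-force
oracle grids are ≤ 32³ with 20 random cases, and branch-count
enumeration uses 50 random multigraphs of ≤ 12 nodes. These sizes
exercise every code path at full working resolution while keeping a
complete validation run within a few minutes on one CPU.

## Known limitations

* The insideness statistic cannot close wall holes on vessels whose
  radius approaches the voxel size (see above).
* Sibling branches that stay within the skeleton's resolving distance
  for most of their length can merge; in the recovery battery this is
  the single residual failure mode (≈ 1 phantom in 40).
* The per-segment diameter convention, junction placement at the clique
  centroid and the collapse thresholds are validated against phantoms,
  not against an independent measurement of real vasculature.
* No curvature/tortuosity metrics, no flow or oxygenation modelling, no
  machine-learned segmentation, and no multi-channel handling.
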