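# Methods

This note documents the models and procedures implemented in `axialquant`,
the choices made where the underlying quantification left details open, and
what the synthetic benchmarks do and do not establish.

## 2.5D nucleus consolidation (`axialquant.consolidate`)

Confocal stacks are segmented plane-by-plane by an upstream 2D detector;
this package reassembles the per-plane instance masks into 3D nuclei.

**Link graph.** Masks in nearby planes are linked when their overlap
fraction reaches `overlap_min` (default 0.30, inclusive). The overlap
fraction uses the *smaller* mask's area as denominator,
`|A∩B| / min(|A|, |B|)` — the convention most tolerant to nuclei tapering
off in z, where the terminal slice is much smaller than the equatorial one.
Links are restricted to consecutive planes (|Δz| = 1); `max_plane_gap` can
be raised (e.g. to 2) so that a single missed detection plane does not cut
a nucleus in two. Each edge carries the Jaccard distance
`1 − |A∩B|/|A∪B|` between the linked masks.

**Components and size thresholds.** Connected components of the link graph
are candidate nuclei. Two node-count thresholds govern pruning:
`t_typical`, the typical number of planes a single nucleus spans, and a
hard cap `t_max`. Both must be configured per dataset; for synthetic scenes
the package derives `t_typical = ⌈2 × median true z-extent⌉` and
`t_max = 2·t_typical`. Components at or below `t_typical` are accepted
untouched.

**Ordered pruning.** Oversized components are split by removing edges in a
fixed order:

1. once per component, delete *all* edges with Jaccard distance above
   `jaccard_purge` (default 0.7);
2. while two member masks share a plane (a physical impossibility for one
   nucleus), delete the worst-distance edge incident to any such conflict;
3. otherwise delete the worst edge while its distance exceeds
   `low_distance_guard` (default 0.2);
4. if the component still exceeds `t_max` and every remaining distance is
   at or below the guard, delete one uniformly random edge (seeded
   generator, seed recorded in output metadata);
5. a component at or below `t_max`, with no same-plane conflict and no
   distance above the guard, is accepted as one nucleus.

Determinism is part of the contract: ties on distance break toward the
lexicographically smallest `(plane, label)` endpoint pair; sub-components
are processed first-come-first-served ordered by their smallest node; the
random rule draws an index into the sorted edge list. Two runs with the
same seed are byte-identical. A dedicated naive re-implementation of these
rules (recomputing everything at every step) serves as an oracle in the
test suite and agrees with the production code on 1,000 random components.

Single-plane components are kept as nuclei by default (`min_planes_keep =
1`); an optional filter removes shallow detections.

**Features.** Per nucleus: unweighted voxel centroid (µm, origin at the
image corner), volume (voxel count × pixel_size² × z-spacing), plane count
and the arithmetic mean of each intensity channel over the voxel mask.

## Synthetic scenes (`axialquant.synthetic`)

The generator provides ground-truthed stand-ins for the two imaging
preparations: disc-shaped micropatterned colonies and elongated capsule
(stadium-footprint) organoids.

**Geometry and packing.** Nuclei are axis-aligned ellipsoids with xy
semi-axis ~N(4, 0.5²) µm (typical pluripotent-epithelium nucleus) and a
mild random z-anisotropy factor (clipped N(1, 0.1²)). Placement is
rejection sampling with *cylindrical* (xy) exclusion: no nucleus may sit
directly above another, as in an epithelial sheet. This also makes
noise-free scenes exactly consolidatable — the generator's round-trip
contract — because xy-overlapping stacked nuclei would be inherently
ambiguous to any plane-linking method. Infeasible packings raise an error
naming the achieved count. Default raster: 1 µm lateral pixels, 1 µm
z-steps, 16 planes, so nuclei span ~8 planes.

**Classes and intensities.** Named zones assign marker intensity means by
normalized radius (disc) or by normalized axial/transverse position
(capsule): a TBXT-high edge ring (r/R ≥ 0.8), SOX2-high centre (r/R < 0.5)
and a double-positive intermediate ring for colonies; a midline reporter
stripe of configurable axial coverage flanked by floor-plate and dorsal
zones for organoids. Per-nucleus means get log-normal cell-to-cell
variability (CV 0.1); voxels get Gaussian noise (σ = 3 on means of order
10–150); reporter stripes are additionally painted into the pixel
background so that the stripe's axial extent is exact to one voxel.

**Imperfect detections.** `emit_detections` slices each nucleus plane-wise
and applies, per (nucleus, plane): misses, splits (bisection across the
longer axis) and boundary jitter (±1 px dilation/erosion); then merges
abutting mask pairs from different nuclei within a plane. Every emitted
mask maps to its dominant true nucleus; merge and split products are
flagged, and event counts are recorded so tests can verify the empirical
rates against their binomial confidence bounds.

**What the generator does not model.** Point-spread blur, depth-dependent
attenuation, nuclear texture, mitotic figures, genuinely 3D (multi-layer)
tissue, or detector errors correlated across planes. Passing recovery
benchmarks therefore demonstrates algorithmic correctness under the stated
error model, not detector-grade performance on real stacks.

**2D organoid fixtures.** Curved-capsule masks are rasterized as the set of
pixels within `width/2` of a generating polyline; each pixel's standardized
position is computed by continuous nearest-point projection (a rasterized
centerline skews the foot point of far-off-axis pixels by several pixels).
The standardized coordinate is normalized over the tip-to-tip length
(centerline + one cap radius per end), matching how a measured midline
spans the mask extremities. Cohorts draw stripe coverage from
N(0.371, 0.199²) truncated to [0, 1], centred on the long axis, with
lengths ~N(1.26, 0.25²) mm — the scale of day-7 elongated trunk organoids.

## Marker quantification (`axialquant.markers`)

Intensities are classified into three levels. With manual thresholds
`(t1, t2)`: absent < t1 ≤ low < t2 ≤ high. Automatic thresholds fit a
3-component Gaussian mixture to log(value + 1) and cut where the posterior
assignment switches component (grid of 4,096 points between the data
extremes); if the components do not separate, quantile cuts (defaults 50%
and 90%) are used instead, and the fitted thresholds are always reported.
Classification is by thresholding, never by per-cell posterior, so the map
from intensity to level is monotone by construction. All-identical inputs
fall back to "absent" when at or below the configured background, and raise
otherwise (automatic cutting would be meaningless).

Gates are configuration-defined predicates over levels (defaults: SOX2
alone, TBXT alone, double-positive, with an implicit exhaustive "other");
the gate set must be mutually exclusive and any overlap on a concrete cell
is a configuration error. Composition summaries report per-colony class
proportions and across-colony Tukey box-plot statistics: linear-interpolation
("type 7") quartiles, whiskers at the most extreme values within 1.5×IQR of
the nearer hinge, points beyond flagged as outliers.

## Spatial mapping (`axialquant.spatial`)

Clustering is k-means (default k = 4) on z-scored log(signal + 1), seeded
and deterministic; degenerate input (all cells identical) is flagged rather
than split arbitrarily. Cluster assignments are joined to the 3D centroids
for plotting. Nearest-distance analysis computes, per source cell, the
Euclidean 3D distance (µm, so anisotropic z is honoured) to the closest
cell of each of two target classes, and compares the paired per-cell
distances with a two-sided Wilcoxon signed-rank test; class means and
medians are reported alongside the test.

## Colony profiling (`axialquant.colony`)

Radial profiles bin pixels (or cell centroids) by normalized radius r/R
into `n_bins` (default 50) equal-width bins; per-colony bin means are
averaged across colonies with an s.d. band (0 for a single colony); empty
bins are reported as missing, never as zero. Profiles can be computed from
raw pixels or from per-cell records — the nucleus-pipeline analyses are
cell-based, stain quantifications pixel-based — and both views are exposed.
Colony geometry comes from the nominal micropattern diameter or a
least-squares (Kåsa) circle fit to the boundary.

Peripheral aggregates: marker-high cells (or pixels) with r/R ≥ 0.8 are
grouped by angular connectivity; a gap larger than 15° between consecutive
angles (wrap-around handled) starts a new aggregate, and groups smaller
than `min_cells` (default 3) are ignored. Both the gap and the band are
configuration, since "aggregate" has no canonical computational definition.

Time-course normalization: per gene, log10(value + pseudo-count) divided by
the gene's maximum, so the peak time point is exactly 1; all-zero genes are
flagged undefined rather than divided by zero.

## Organoid morphometrics (`axialquant.morph`)

**Midline.** The midline is the longest geodesic path on the morphological
skeleton, found by a double Dijkstra sweep (exact on tree-shaped
skeletons). Near the tips the skeleton forks toward the rounded-cap
corners; the fork region (about one tube half-width) is trimmed so the tip
extension follows the axial direction. The path is smoothed over the
half-width scale, resampled at coarse arclength steps (half-width / 2) to
suppress pixel-scale wobble, and extended to the mask boundary along the
end tangents, so the midline spans the mask extremities and its arclength
is the organoid's maximum length. Masks thinner than ~3 px fall back to the
principal-axis chord with a warning; near-round masks (skeleton collapsed
to a point) likewise use the chord, which makes the length of a disc its
diameter.

**Standardized profiles.** Every in-mask pixel is assigned to its nearest
midline point; each of `n_bins` bins (default 100 for heat maps; recovery
benchmarks use 50) takes the *maximum* signal among its pixels — the
profile of the brightest structure in the cross-section, insensitive to how
much dimmer tissue surrounds it. Empty bins are linearly interpolated and
flagged. Because a midline has no intrinsic direction, profiles are
oriented so the brighter half lies at lower s, making samples comparable; a
mirrored mask therefore yields the same oriented profile. Bin membership
makes the longest-stretch estimate granular at 1/n_bins, and max-pooling
lights up a boundary bin whenever the stripe touches it, so recovered
stretch is accurate to about one bin.

**Statistics.** The longest uninterrupted positive stretch uses a
configurable positivity threshold; when none is given, the midpoint of a
2-component Gaussian mixture over the per-bin maxima separates background
from signal. The conservative bright-area fraction thresholds at the 99th
percentile of in-mask signal by default (a stand-in for an unreported
"conservative segmentation"; always overridable, and recovery benchmarks
pass an explicit threshold between the generated background and signal
levels). Correlations are Pearson product-moment with two-sided
t-distribution p-values; zero-variance inputs are flagged undefined.
Volume-fraction ratios are element-wise with zero denominators flagged
undefined and excluded from cohort summaries.

## Problem sizes used in the benchmarks

Recovery benchmarks run at sizes chosen to make the statistics meaningful
while keeping the whole suite quick on one CPU: 20 noise-free scenes of
50–500 nuclei (disc and capsule), 20 noisy disc scenes of 200 nuclei
(split 0.10 / merge 0.05 / miss 0.05, ±1 px jitter, consolidated with
`max_plane_gap = 2`), 1,000 random pruning components, mixtures of 3,000
cells × 10 seeds, one 8,000-cell colony, 50-organoid cohorts, and a
3,000-nucleus zoned capsule (1.6 × 0.4 mm) for the distance analysis
(≥ 200 source cells).

## Known limitations

- The pruning thresholds `t_typical`/`t_max` must reflect the true nucleus
  z-extent; badly chosen values either merge stacked nuclei or shred tall
  ones. They are dataset configuration, not constants.
- The automatic three-level thresholds are a mixture-model stand-in for
  manually curated cuts; on strongly skewed or unimodal marker
  distributions the quantile fallback engages and should be reviewed.
- Midline extraction assumes one dominant elongated component; rings or
  branched organoids violate the longest-path model (the largest component
  is used, with a warning, and branches are ignored).
- Distances are between nucleus centroids, not membrane surfaces; reported
  separations include ~one cell radius of offset.
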