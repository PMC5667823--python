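# Methods

## Uncertainty model

Prior knowledge is encoded per feature as a trapezoidal membership
function μ(x; a, b, c, d) = max(min((x−a)/(b−a), 1, (d−x)/(d−c)), 0).
Degenerate edges (b = a or d = c) drop the corresponding term from the
inner minimum instead of evaluating 0/0, which realises rectangular
membership functions and singletons. Several features describing one
linguistic term are combined with a t-norm; all three classical t-norms
are implemented (minimum, product, bounded difference) and satisfy the
pointwise ordering bounded difference ≤ product ≤ minimum. The default
is the minimum operator, so a combined FSMD always equals the membership
of the feature that deviates most from expectation. Partitions of a
feature axis are built only from explicit user configuration; the
package never infers multi-term partitions from data.

Each operator carries two thresholds. The forward threshold α rejects
outputs with FSMD < α. The backward threshold β ∈ [α, 1] controls the
propagation set: predecessor rows whose outputs came out uncertain
(α ≤ FSMD < β) are carried along to the next operator, which may use
them to repair flaws. Parent links between an operator's outputs and its
inputs are supplied explicitly by the operator; the framework validates
and unions. Carried rows keep their provenance tag so filtered and
carried subsets stay disjoint.

## Pipeline operators

**Seed detection.** The image is filtered with a bank of
scale-normalised (σ²-weighted) negated Laplacian-of-Gaussian kernels;
the per-voxel maximum over scales is the detection landscape. Scales are
sampled geometrically (5 steps) across the expected radius range and
mapped to σ by σ = r/√3, the location of the 3-D LoG response maximum
for a ball of radius r (verified against a brute-force σ sweep in the
tests); the alternative convention σ = r/2 is selectable. Anisotropy is
handled by per-axis σ factors. Extrema use 26-connectivity; the
non-strict mode (≥ instead of >) additionally captures intensity
plateaus and is a strict superset of the strict mode. Only positive
responses are candidates. Background detections are removed by
thresholding the mean intensity of a cube window (half-width
round(r_min/2), clipped at borders) at t_wmi; an automatic fallback
(Otsu split of the candidate window means) is provided as an extension
for unattended runs. Redundant detections are fused by Ward-linkage
clustering on (x, y, z) cut at t_dbc = r_min, replacing each cluster by
its feature-vector mean. Seed FSMDs combine window mean, maximum window
intensity and z-position memberships with the minimum operator; the
z trapezoid decays with distance from the detection objective but stays
positive inside the stack, and is mirrored for the opposing view. The
forward threshold is α = 0.0001 — slightly above zero, so only
certainly-false detections (membership exactly 0) are dropped.

**Segmentation.** Global Otsu thresholding (the above-threshold class is
foreground) followed by 26-connected component labelling. Size features
(volume and inclusive bounding-box extents) receive FSMDs from
trapezoids fitted as (min, 5%-quantile, 95%-quantile, max) of reference
region statistics — on the simulated benchmark these are taken from the
ground-truth label volumes, mirroring how the reference parameterisation
was derived from benchmark feature histograms. A low-FSMD component is
classified by its most-deviating feature against the plateau boundaries:
below b → smaller than expected, above c → larger. Components flagged
*larger* than expected with FSMD < β are cropped (2-voxel margin) and
split by a seeded watershed on the negated smoothed intensity (distance-
transform landscape selectable) restricted to the component mask, using
the detected seeds inside the mask as markers; components with fewer
than two interior seeds are left unchanged, and the voxel set is always
preserved and partitioned. The non-guided baseline applies the watershed
to every multi-seed component instead. After splitting, labels are
re-identified and FSMDs re-evaluated. Finally, components with FSMD <
α = 0.1 that are *smaller* than expected are removed. Larger-than-
expected components that could not be split are deliberately kept: they
still carry seeds that the tracking stage can fall back on (removing
every record below α is available as a mode switch).

**Multiview fusion.** Opposing views are generated on one grid, so no
registration is needed. Binary fusion is the voxelwise maximum. The
segment-based fusion is a reconstruction (the original description is
not available in detail): per-frame region tables of the two views are
matched one-to-one, greedily by ascending centroid distance within a
match radius (default r_min), and each matched pair keeps the record
with the higher FSMD; unmatched records pass through. An alternative —
merging voxel masks instead of selecting records — would also be
consistent with the published behaviour; record selection was chosen for
its simplicity and because it preserves per-view provenance.

**Tracking.** Every object in frame t links to its Euclidean-nearest
object in frame t+1 (physical coordinates via the voxel spacing);
many-to-one links are allowed and surface as merged-track errors.
Distance ties break toward the lowest candidate id so runs are
deterministic. The uncertainty-aware variant builds the per-frame node
set as: segments with FSMD ≥ β = 0.9, plus the seed points contained in
the masks of segments below β; seeds falling on background are kept as
orphan nodes rather than silently dropped. With β = 0 the variant
reduces exactly to plain nearest-neighbour tracking. No gap closing,
division detection or maximum link distance is applied by default (an
optional cutoff exists). Track ids follow linkage chains; a node with
two or more incoming edges starts a new track and is recorded as a merge
event.

## Benchmark simulator

The simulator emulates an epiboly-stage embryo: ellipsoidal nuclei
confined to a shell between an inner and an outer bounding surface of an
axis-aligned ellipsoid, initialised in a polar cap around the animal
pole and drifting toward the vegetal pole, with tangential Brownian
jitter, soft pairwise repulsion and divisions at per-object jittered
times (children appear at ±0.7 r along a random tangent). Repulsion
targets a centre distance of 1.3 × (r_i + r_j): nuclei sit inside cells,
so their spacing exceeds the summed nuclear radii, leaving visible
cytoplasm gaps with occasional near-contacts in dense regions. Default
nucleus semi-axes are 9.3 ± 0.7 voxels in-plane and 2.9 ± 0.25 in z
(flattened by the coarser axial sampling), giving rendered volumes,
widths, heights and depths in the reference statistical ranges
(volume ≈ 450–2000 voxels).

Rendering rasterises each nucleus as a soft-edged intensity ellipsoid
(plateau 1, decaying over 15% of the normalised radius) and a solid
label; overlaps resolve to the nearest centre in radius-normalised
coordinates. The acquisition model applies, in order: multiplicative
attenuation exp(−λ·z) with z measured from the view's objective
(λ = 0.004/voxel), Gaussian PSF blur (σ = 1, 1, 0.6 voxels in x, y, z),
dark current (0.02), Poisson shot noise at 400 photons per unit
intensity, additive Gaussian noise (σ_agn = 0.001 for the low-noise
profile) and a clip to [0, 1]. Two opposing views differ only in their
attenuation direction and noise draws. Profiles cover single frames with
varying object counts, additive-Gaussian and Poisson noise sweeps, and
two-view time series with divisions. All randomness derives from one
integer seed; identical seeds give byte-identical outputs.

What the simulator does *not* emulate: nucleus texture (objects are
plateau ellipsoids, not textured chromatin), refractive or scattering
optics beyond exponential attenuation, rotation-based multiview
misregistration, photobleaching, and cell shape. Passing scores on this
benchmark therefore show that the uncertainty machinery works as
designed under controlled degradations — not that the pipeline matches
its behaviour on real light-sheet data, where texture, registration
error and spatially varying background make every stage harder.

## Evaluation

Detection matching is greedy, ascending by distance, one-to-one, within
a radius (default r_min; on these benchmarks matched distances average
well below 2 voxels, and the greedy matching agrees with optimal
bipartite matching in the tests). The Rand index is computed over voxel
pairs drawn from the union of the foregrounds (exact when the pair count
is small, a 10⁵-pair subsample otherwise) — note this foreground
restriction makes the score far more discriminative than a whole-volume
Rand index, which background agreement dominates. Topology errors use
majority-overlap rules: a predicted object with more than half its
voxels on reference background is *added*; each reference object is
assigned the predicted label covering the plurality of its voxels, or is
*missing* when background covers the majority; extra references absorbed
by one prediction count as *merged*, extra predictions majority-inside
one reference as *split*. Precision, recall and F-score treat split and
added objects as false positives, merged and missing as false negatives.
The Jaccard index, normalised sum of distances and Hausdorff metric are
averaged over matched pairs, with distances measured from the reference
object's boundary on a local window (the reference bounding box padded
by its own extent, so grossly oversized predictions are judged locally).

Tracking scores assign reference nodes per frame to their nearest
predicted node within the match radius (many references may share one
prediction). Edge true positives are predicted edges whose endpoints
carry a matching reference edge. The TRA measure follows the acyclic-
oriented-graph-matching formulation: TRA = 1 − min(AOGM, AOGM₀)/AOGM₀
with default edit weights NS = 5 (vertex split), FN = 10, FP = 1,
ED = 1 (redundant edge), EA = 1.5 (missing edge), EC = 1; AOGM₀ is the
cost of building the reference from an empty graph. Because node
correspondence here is centroid-based rather than mask-overlap-based,
these scores are exact for within-package comparisons but not
necessarily identical to implementations that match by voxel overlap.

## Problem sizes and numerical choices

The replication workflows use five single-frame replicates of ~200
nuclei on a 256×256×64 grid and three two-view, ten-frame series of
~150 nuclei on a 192×192×56 grid — a single-workstation scale chosen so
the whole suite regenerates its data from scratch in minutes. Quantiles
use linear interpolation (the common default; exposed as a parameter).
Labels are written as 16-bit TIFF and widened internally when needed.
Empirical tolerances in the tests (5% on noise moments, 5% on rendered
ellipsoid volumes, 95% voxel agreement between the watershed and a
nearest-seed oracle) reflect discretisation, not model freedom.

## Known limitations

Global Otsu only (no block-local adaptation); no gap closing or division
classification in the tracker; the segment-based fusion rule is a
documented reconstruction; PSF-shape-based uncertainty is out of scope.
Carried propagation rows with differing feature schemas are united on
the shared identity columns with missing values padded, a case the
pipeline itself never produces.
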