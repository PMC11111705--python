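# Methods

This note documents the model behind the package, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic phantoms do and do not establish about real microscopy
data.

## The segmentation model

The working assumption is purely topological: a neuron in a fluorescence
stack is a connected set of bright voxels whose intensity profile is
locally concave, bounded by a shell where the profile is convex. The
discrete curvature along each axis — the central second difference with the
[1, −2, 1] stencil, unit voxel spacing — captures this: D² < 0 along every
axis inside a structure, D² > 0 along the surface normal on the outer
border. No model of the signal amplitude, PSF or noise distribution enters;
the method only asks K-means to find the natural groupings of voxels in the
4-D space (I, D²x, D²y, D²z) and then reads the signs of the per-class
derivative means.

Intensity is always taken from the unsmoothed stack; the derivative
channels come from the stack smoothed with an isotropic Gaussian of
standard deviation σ voxels (σ = 0 means no smoothing). Each channel is
z-scored over the foreground before clustering — with raw units the
intensity channel (range 10³–10⁴ for 16-bit data) would dominate the
squared-Euclidean metric and the derivative channels would be decorative.
Class statistics are always reported in original units, so the sign-based
selection rules are unaffected by the standardization; a switch
(`standardize_features`) restores the raw-space behaviour for comparison.

### Choice of K

K is the smallest integer (searched ascending from 2, default ceiling 10)
whose partition contains, for each axis, a class attaining the maximal mean
second derivative that is (a) strictly positive and (b) a *different* class
for each of x, y, z. Requiring distinct border classes is what makes the
criterion scale-aware: with too few classes the borders of all orientations
collapse into one mixed cluster. Two consequences discovered on the
phantoms and worth stating plainly:

* The criterion is only satisfiable when the image contains surfaces of
  genuinely different orientations whose border voxels are axis-pure —
  structures several voxels thick, elongated along different directions.
  On a perfectly isotropic object (a single sphere) the three argmax
  classes coincide by symmetry at every K and the search correctly reports
  failure; a fixed K remains available for such degenerate inputs.
* Derivative noise must be below the border signal. Shot noise passes
  through the [1, −2, 1] stencil with variance amplified ×6, and K-means
  then partitions the noise cloud by sign octant, again collapsing the
  argmax classes. Smoothing the derivative channel (σ ≈ 1.5 voxels on the
  phantom conditions) restores the criterion; multi-scale runs exist
  precisely because one σ rarely suits both thin processes and thick
  somata.

On the three-axis tube phantoms the search settles at K = 6–7, with the
border classes in the middle of the intensity ranking and the neuron body
in the top classes — the same qualitative layout the method produces on
real confocal data.

### Class selection and postprocessing

Classes whose three mean second derivatives are all strictly negative (in
original units) form the neuron mask; class 1 — the dimmest, which absorbs
homogeneous background — is never selected, and a warning is raised if the
selection is not the top of the intensity ranking. "Strictly negative" is
parameter-free on purpose: any margin would be a hidden threshold.

Per-scale binary masks are merged by voxelwise OR, then postprocessed once:
3-D hole filling (background components not 6-connected to the volume
border become foreground — intensity dips inside somata read as borders and
punch cavities) followed by removal of 26-connected components under
`min_cluster_voxels` = 7 voxels, the smallest 3-D-symmetric structure.
Running the pruning after the merge prevents one scale from resurrecting
another scale's rejected specks. The 26/6 connectivity pairing for
foreground/background is the standard duality that avoids checkerboard
paradoxes.

### Background threshold

The threshold's only job is to shrink the clustering problem; it must not
pre-decide the segmentation. The default is therefore permissive — keep the
brightest 25% of voxels (`percentile`, 75). Otsu and absolute thresholds
are available but Otsu in particular is a poor default here: on sparse
neural stacks it places the cut inside the blurred border shell and deletes
the positive-D² voxels that the K-selection criterion needs.

### K-means settings

Best of 10 replicates (fresh k-means++ starts under one seeded generator),
at most 1000 Lloyd iterations each, lowest within-cluster sum of squares
wins; deterministic given `random_seed`. For stacks too large to cluster
whole, `fit_on_crop_apply_full` learns centroids, standardization and class
selection on a crop and labels the full volume by nearest centroid — exact
when the crop is statistically representative (full-vs-crop Dice ≥ 0.95 on
homogeneous phantoms).

## The parcellation model

Separation and spine grouping are the same computation: a topographic
partition of the volume around *cores*. The grayscale stack is
median-filtered (3×3×3, reflection padding, voxel space regardless of
anisotropy), complemented as `max − filtered`, and all regional minima
except those at the cores are erased by erosion-type morphological
reconstruction (marker at the global floor on cores, ceiling elsewhere,
reconstructed under `min(surface + h, ceiling)` with h = max(1, 0.1% of the
range)). After imposition the surface has regional minima exactly at the
cores — verified by exhaustive local-minimum scan in the tests — so the
26-connected watershed floods exactly one basin per core, with no unlabeled
ridge voxels (ridges join the basin that reaches them first; the separate
`watershed_lines` volume records the boundaries).

Cores come from user markers (CSV of voxel coordinates; each dilated to a
ball of radius 2 voxels so a single click forms a robust well) or, in the
super-resolution regime, automatically as the mask components at or above
`core_size_threshold` voxels; smaller components are spine clusters.
Whole-cluster assignment uses the majority basin, with ties broken by the
basin under the cluster centroid, then the lowest core label — a detached
spine head is one object and should not be split by a ridge that happens to
graze it. Only components containing two or more cores (genuinely merged
neurons) are split voxelwise along basin boundaries. Post-hoc correction
re-runs the parcellation with extra markers added to the core set, the
remedy for branches whose soma lies outside the acquired volume.

## Skeletonization and SWC

Per-neuron masks are thinned by topology-preserving 3-D thinning (in voxel
space; anisotropy enters only through physical edge lengths
√(Δz²dz² + Δy²dy² + Δx²dx²)). Every skeleton voxel is a node; 26-neighbours
are edges. Cycles — thinning artefacts around thick junctions or genuine
loops from touching branches — are cut by keeping the maximum-weight
spanning tree under edge weight min(endpoint intensities): every edge
removed from a cycle is one of its dimmest, which is where spurious
bridges live. Ties prefer removing the longer edge, then lower node ids;
the result is verified against exhaustive spanning-tree enumeration on
small graphs. The tree is rooted at the node nearest the soma marker and
written as standard 7-column SWC in µm (root type 1, dendrite type 3,
parent ids preceding children).

Node radii default to the Euclidean distance transform of the mask at the
node (`radius_mode="edt"`), a geometric half-thickness that is exact on
tube phantoms. An intensity-proportional mode exists
(`radius_mode="intensity"`, radius = intensity / max × calibration) for
workflows that calibrate diameter against brightness, but no universal
intensity→diameter map is defensible, so the calibration factor is left to
the user and the geometric mode is the default.

## Morphometrics

**Strahler.** The tree is decomposed into segments (maximal chains between
root, branch points and terminations; each non-root topological point owns
the chain up to, excluding, its nearest topological ancestor) and orders
assigned by the classical centripetal recursion: terminal segments order 1;
at a junction, order s + 1 if two or more children attain the maximal child
order s, else s (the ≥ 2 rule is the standard multifurcation
generalization). Branches are maximal runs of same-order segments — well
defined because at most one child can share its parent's order. The
per-order table covers segment/branch counts (raw and normalized), mean
lengths and diameters, bifurcation ratios numBr(i)/numBr(i+1), normalized
topological subtree sizes, total and per-order cable length, and
least-squares (slope, intercept) fits of the normalized counts against
order. The fits use log10 counts by default — segment counts decay
geometrically with order, so the log-linear slope is the informative
number — with natural-log and linear scales as options; with a single order
the fit is undefined and reported as such rather than extrapolated.

**Sholl.** Computed on the tree, not the voxel mask: crossings(r) = number
of edges whose endpoint Euclidean distances to the root straddle r. The tie
convention is d_near ≤ r < d_far: a sphere passing exactly through a node
crosses that node's outgoing edge once, and an arbor tip exactly at radius
r does not count. This keeps the hand-computable identity for a straight
10 µm path probed at 1..10 µm — profile 1,1,…,1,0, trapezoidal AUC 8.5 —
and makes the AUC additive over disjoint subtrees at the root. With
per-voxel nodes an edge can straddle at most one sampling shell per step,
so straddle counting equals true sphere-crossing counting.

**Masks.** Dice = 2|A∩B|/(|A|+|B|), with two empty masks defined as 1 (and
a warning). Surface area sums exposed voxel faces with their physical
areas — exact for blocky shapes, an overestimate (up to ×1.5) for smooth
curved surfaces, which is acceptable because the quantity is used
comparatively; an iso-surface mesh could replace it where absolute areas
matter. Volume is voxel count × voxel volume.

**Spines.** A truth spine counts as detected-and-assigned (TP) iff some
predicted spine cluster contains its centre and carries the parent
dendrite's label; a cluster can redeem at most one centre (nearest to its
centroid); a detection assigned to the wrong dendrite is both a miss and a
false alarm. S% = 100·TP/(TP+FN), P% = 100·TP/(TP+FP).

## The phantom generator

Phantoms rasterize constant-intensity geometry — polyline tubes, ellipsoid
somata, spherical spine heads with optional dimmer necks (0.3× contrast by
default, mimicking the near-invisible necks of super-resolution data) — at
plateau 200 over background 20, blur it with an anisotropic Gaussian PSF
(σ = 1.2 voxels axially, 0.8 laterally, mirroring the axial elongation of
confocal optics), and add mixed noise: Poisson with gain 4 (variance =
4·intensity) plus Gaussian read noise (σ = 3), seeded and fully
deterministic. The defaults give a contrast-to-noise ratio of ≈ 15–18,
typical of a decent confocal acquisition; a `target_snr` option calibrates
the read-noise term (by a short fixed-point loop, because clipping at zero
distorts the closed-form solution) for controlled-SNR experiments. Voxel
size defaults to (0.5, 0.25, 0.25) µm.

All ground truth — per-neuron masks, core markers, spine centres with
parent labels, centerline SWC — derives from the pre-noise geometry.
Neurons may overlap; overlaps are recorded in a contact map because they
are exactly what the separation step is tested on.

What the phantoms do *not* emulate: depth-dependent attenuation and
scattering, uneven labelling along a cell, autofluorescence textures,
deconvolution artefacts, curved/branching dendrites with tapering radii,
and realistic Purkinje-scale arbor complexity. Passing the phantom battery
therefore establishes that the algorithms are implemented correctly and
behave as designed under controlled imaging physics — not that any fixed
parameter set transfers to a given real dataset, where σ, the threshold and
the core size threshold remain per-dataset choices.

## Test problem sizes

The test suite and the acceptance script run on deliberately small
instances chosen so the whole battery completes in minutes on one CPU:
phantom volumes of 48–64 voxels per side (≈10⁵–10⁶ voxel clustering
problems), 20 seeded end-to-end phantoms, 100 random clustering instances
up to 5000 points, 200 random trees up to 200 nodes, exhaustive
spanning-tree enumeration up to 10 nodes. The algorithms contain nothing
size-specific; larger stacks only cost time and memory (K-means and the
watershed are the dominant terms, and `fit_on_crop_apply_full` exists for
stacks where full-volume clustering is impractical).

## Known limitations

* Automatic K selection requires oriented, resolvable structure and
  moderate derivative noise; it reports failure (with per-K diagnostics)
  rather than guessing on isotropic or noise-dominated input.
* The sign-based class selection has no confidence margin; a class whose
  derivative means hover at zero flips in or out under resampling. The
  multi-scale OR-merge softens this in practice.
* Skeleton-based Sholl and Strahler inherit thinning artefacts (short spur
  branches) on noisy masks; no spur pruning is applied, by design — it
  would be a second, hidden morphology filter.
* Spine *necks* are not reconstructed; detached heads are only grouped
  with a dendrite. Neck inference is out of scope.
* The watershed is computed once per stack; no tiling for volumes that do
  not fit in memory.
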