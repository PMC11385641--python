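# Methods

This note documents the measurement models implemented in `woundquant`,
the defaults that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-scene tests do and do not
demonstrate about real microscopy data.

## Image model and calibration

All stages operate on calibrated intensity arrays in canonical
`(channel, t, z, y, x)` order with a strictly positive voxel size
`(dz, dy, dx)` in µm. Filters and structuring elements work in pixel
units per axis; every reported volume, area and length is converted to
physical units through the voxel size (volume = voxel count × dz·dy·dx,
with 2D images treated as single-slice stacks so areas extrude
consistently). Anisotropic voxels are therefore handled exactly for
measurements and only approximately for isotropic filters, which is the
standard trade-off when z sampling is coarser than xy.

## Detection

The detection chain is: optional prefilter (2D median applied slice-wise
so focal planes do not mix, or nD Gaussian), automatic threshold with a
user multiplier and a minimum permitted floor, connected components,
optional watershed split, physical-volume size filter.

- **Thresholds.** `otsu` maximizes between-class variance on a 256-bin
  histogram; `moments` is Tsai's moment-preserving method (the "Moments"
  algorithm of the classical thresholding literature), implemented on a
  256-bin histogram because scikit-image does not provide it. The final
  threshold is `max(multiplier · t_auto, floor)`; the floor prevents
  background segmentation when a channel is nearly empty. Foreground is
  `intensity ≥ threshold` (inclusive), which makes the two-valued
  histogram case unambiguous. A constant image has no automatic
  threshold and raises "degenerate histogram" — except inside
  `detect_objects` when a positive floor is set, where the floor alone
  defines foreground so an all-zero stack cleanly yields zero objects.
- **Connectivity.** "Contiguous" regions use full connectivity
  (8-connected in 2D, 26-connected in 3D), the default of the labelling
  operators common in this field's toolchains.
- **Size filter.** Objects below `min_object_volume` (µm³) are removed;
  the filter is monotone (raising the cutoff never adds objects) and the
  survivors are always a subset.
- **Watershed split.** Seeds are the regional maxima of the
  Gaussian-smoothed intensity (σ = 1 px default) within each object;
  adjacent maxima on a plateau collapse to a single seed so flat-topped
  objects do not over-split. The watershed on the inverted smoothed
  intensity is masked to the original foreground, so the output is a
  pure partition: voxel counts are conserved exactly.
- **Background subtraction.** True rolling-ball (scikit-image's
  implementation), applied slice-wise for stacks, with the result
  clamped at zero. A narrow peak on a flat background survives within 5%
  of its height for ball radii much larger than the peak width.

## Colocalization and regions

A cargo voxel is *inside* iff it coincides with a nonzero cell label, so
inside + outside volumes partition the total cargo volume exactly. The
"contains cargo" default is any overlap (≥ 1 voxel), the most permissive
reading and monotone in the exposed `min_overlap_um3` parameter.

Regions of interest are 2D shapes (circle, polygon, whole image) in µm
coordinates, extruded through z as cylinders for stacks. Objects are
assigned to a region by their centroid — a region counts whole cells, not
partial overlaps — and that rule is exposed rather than hidden. An empty
region makes a percentage undefined; it is flagged as NaN, never reported
as 0. Manual curation of wrongly detected objects is supported in batch
form as an id exclusion list.

Time courses average the signal channel over each surviving cell
(cells below `min_cell_area_um2` are dropped per frame), then across
cells; the area under the population curve is trapezoidal over its
defined frames, which is exactly additive over subintervals and linear in
the signal.

## Tracking

Nuclei are detected per frame with Gaussian smoothing, rolling-ball
background subtraction, the moments threshold and watershed splitting.
Linking is deterministic greedy globally-nearest-pair assignment per
frame transition: candidate pairs within `max_link_distance_um` are taken
in increasing distance, ties broken by earlier detection index then
earlier track id. Gap closing defaults to 0 frames. A published global
assignment (LAP) tracker would differ on crossing trajectories; the
greedy rule is chosen because it is reproducible and oracle-checkable,
and the test fixtures are non-crossing by construction.

Per track, velocity is the mean speed L/T (path length over duration) —
the net-displacement velocity D/T is also emitted — and the
directionality ratio is D/L ∈ [0, 1]. Single-sample and zero-length
tracks have undefined metrics, flagged as NaN. Tracks shorter than 3
samples are excluded from population summaries by default.

## Vessels

Probability maps are binarized at 0.5 (inclusive), cleaned by n
iterations of dilation then erosion followed by hole filling, and
fragments **strictly larger** than 100 µm³ are kept (literal reading of
"larger than"). The skeleton (medial axis) is converted to a graph:

- voxels with ≠ 2 skeleton neighbours are node voxels; adjacent junction
  voxels (≥ 3 neighbours) merge into one junction node, otherwise node
  counts would depend on voxel parity;
- branches are chains of 2-neighbour voxels between nodes, with geodesic
  length summed over physical voxel steps;
- single-voxel spurs hanging directly off a junction cluster are pruned
  as digitization artifacts (disclosed because it changes counts);
- a pure cycle yields one synthetic node with a self-loop.

A **sprout** is an edge that (1) has a single connection to the skeleton
(one endpoint is an end node), (2) is not the product of clipping at the
image border — its free end lies farther than `border_margin_px`
(default 2) from every image face — and (3) is shorter than the user
cutoff. Note that skeletonization retracts tube ends by roughly the tube
radius, so detecting border clipping reliably needs a margin of at least
the vessel radius; the summary JSON reports junction-cluster count
(canonical "nodes"), junction voxel count and junctions-plus-ends, since
tools differ on which of the three they report.

Skeleton lengths on synthetic tubes are accurate to within the end
retraction (a 100 µm cylinder of radius 3 px measures ≈ 98 µm); the ±10%
recovery band accounts for this discretization, not for estimator
variance.

## Collagen alignment

Local fibril orientation comes from image gradients (Gaussian
derivatives, σ = 2 px): the default backend smooths the structure tensor
at 2σ and takes the fibril axis perpendicular to the dominant
eigenvector, weighting each pixel by the tensor anisotropy; a plain
local-gradient backend (energy = |∇I|²) is available and the two agree
within one bin on stripe fixtures. Angles are axial (period π), measured
counterclockwise from the image x-axis, binned into 90 bins of 2° over
(−90°, 90°].

The histogram is split at 0° into (0, 90] and (0, −90], an isotropic
pedestal (minimum bin weight by default; a percentile alternative is
exposed) is subtracted per range, and each range is summarized by

    θ_th = ½·atan2(Σ w sin 2θ, Σ w cos 2θ)
    AI   = Σ w cos 2(θ − θ_th) / Σ w,  clamped to [0, 1]

the axial mean resultant length about the mean orientation. This form is
pinned to the statistic's boundary semantics: AI = 1 iff all weight
shares one orientation (no angular dispersion), AI = 0 for a uniform
histogram. A range with zero weight after background subtraction is
degenerate and reported as such, never as 0. Both the binned path and a
raw-angle path exist and agree within ±0.01 on 10⁵ von Mises samples.

## Morphometry

Circularity is 4πA/P² clamped to 1. The default perimeter estimator is
the length of the subpixel 0.5-level contour of the Gaussian-smoothed
(σ = 1 px) object mask. This choice was made after evaluating the
alternatives on closed forms: the Crofton approximation reads a digital
40 px square at 0.89 (ideal π/4 ≈ 0.785) and the classic weighted
boundary estimator reads a radius-30 disk at 0.91; the smoothed-contour
estimator lands at 0.99 (disk) and 0.82 (square), inside the expected
bands for both, and decreases monotonically with bar elongation. Crofton
remains available via `perimeter_method="crofton"`.

High-fluorescence volume thresholds the stack at `factor ×` the mean of
a reference region chosen away from the wound (factor default 2.0, a
declared default since no canonical value exists) and counts
suprathreshold voxels inside the wound region; it is monotone
non-increasing in the factor.

Pigmentation uses an all-in-focus projection: per pixel, the z slice
maximizing Gaussian-weighted local variance (σ = 2 px, ≈ 9×9 support)
is selected; the projection is binarized by Otsu and the *dark* fraction
of the region is reported (pigment absorbs in brightfield; a
`bright_pigment` flag inverts the polarity). A uniformly bright field
has no pigment pattern and reports 0%.

Intensity ratios divide the target region's mean by the control region's
mean (error if the control mean is not positive); they are invariant
under global intensity scaling and invert under region swap.

## Synthetic scenes

The generator renders, deterministically given a seed: spheres and
cells-with-cargo (the inside/outside assignment is constructed, not
sampled, so the inside fraction is exact), nucleus movies driven by
persistent random walks (fixed step length = speed × frame interval;
turning angles from a von Mises whose concentration tunes persistence,
κ = 0 giving an unbiased walk), capsule tubes and Y-junctions with
per-branch lengths, fibril fields with axial von Mises orientations
(sampled on 2θ), speckled pigment patches sharp in a single focal slice,
and fracture/control pairs with an exact intensity ratio. Noise, when
requested, is Poisson shot noise at a gain followed by additive Gaussian
read noise (defaults gain 1, σ = 2 intensity units), applied last.

Scene sizes are kept small (≤ 256³ voxels, ≤ 60 frames; e.g. the
default tracking movie is 5 walkers × 30 frames on 128² px, and the
acceptance population is 200 walks of 200 steps) so the full
parameter-recovery suite runs in seconds.

**What passing tests show — and do not.** Parameter recovery on these
scenes validates the measurement definitions and their implementations:
volumes, intersections, graph topology, orientation statistics and
motility metrics are correct on inputs with known truth. The scenes do
not emulate optics (no PSF, no depth attenuation, no photobleaching),
realistic anatomy, segmentation failure modes of the upstream
deep-learning models, or cell crossings and divisions; accuracy on real
stacks therefore still depends on acquisition quality and on the
upstream segmenter where one is used.

## Known limitations

- Tracking is 2D (projected) and greedy; crossing trajectories can swap
  identities where a global assignment would not.
- Skeleton lengths underestimate tube lengths by about one radius per
  free end; sprout-length cutoffs should be read with that bias in mind.
- The rolling-ball and median filters are slice-wise; strongly
  anisotropic 3D backgrounds are not modelled.
- The alignment index is computed on gradient-energy-weighted histograms,
  not on segmented fibril instances; very sparse fields inherit the
  estimator's bias toward rendered edge orientations.
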