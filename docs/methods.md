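# Methods

This note documents the models, algorithms and numerical choices behind
`colonymap`, and what the synthetic-data tests do and do not establish
about real data.

## Virtual slide and consensus segmentation

A region is acquired as an M × N grid of fields of size F px with a fixed
overlap of v px; adjacent field origins differ by exactly F − v px (stage
accuracy is assumed, so no image registration is performed). Pixel
coordinates are 0-based, ordered (row = y, col = x); physical lengths are
px × pixel size. The mosaic of raw images assigns contested overlap
pixels to the field with the smaller grid index — deterministic, and
inconsequential because analysis runs on label consensus, not blended
pixels.

Per-field segmentation label matrices are placed into region coordinates
and duplicate instances of the same physical object are merged. Two
instances from different fields correspond when (a) their region-frame
footprints share at least one pixel and (b) their centroids lie within
one maximum cell diameter. The pixel-overlap test implements the physical
argument that the same object imaged twice occupies the same region
pixels; the centroid guard prevents chained merges of touching
neighbours. Correspondence is applied transitively through a union–find,
which also resolves 4-field corner overlaps by the same larger-area rule.
Of each correspondence group, the largest-area instance is kept (ties:
lower grid index, then lower source label). Objects touching the
outermost 1-px frame of the region are discarded, since such cells are
necessarily truncated.

Containment geometry: in 1-D, a cell of radius r straddling a field
boundary is fully contained in one of the two fields unless its centre
falls in the open interval (F − r, F − v + r), which is empty iff
v ≥ 2r. An overlap of twice the *maximum cell diameter* therefore
guarantees full containment with a 2× safety factor; the brute-force
sweep in the acceptance suite confirms 100% containment at that margin
(and already at one diameter, the tight bound) and failures at half a
diameter.

## Segmentation and features

Colonies: Gaussian blur (default σ = 20 px) merges nuclei into
colony-scale blobs; a global Otsu threshold separates colony from
background; holes are filled and components below a minimum area
(default 2000 µm²) are dropped. Blurring dilates the suprathreshold
support of a compact bright region by roughly σ; an optional erosion
(`erode_px`) compensates when edge distances are measured downstream.
At the sparse cell densities the synthetic generator must use to keep
nuclei separable (~30% foreground), the blur/Otsu boundary additionally
wobbles by roughly ±10 µm with local density fluctuations — about one
cell layer. Real colonies are near-confluent, so this wobble is a
property of the sparse synthetic regime, not of the method on real data;
tests that score layer-band statistics therefore measure context against
the generator's exact colony mask and validate the colony segmenter
separately at the mask-IoU level.

Nuclei: Gaussian smooth (σ = 1.3 µm) → threshold (global Otsu by
default, local mean optional) → Euclidean distance transform →
peak-seeded watershed (seed separation 5 µm) to split touching nuclei →
area filter [15, 500] µm² to discard debris and poorly segmented clumps.
Defaults were tuned on the synthetic generator; on sparse synthetic
fields the segmenter reaches recall and precision ≥ 0.95 (centroid match
≤ 3 µm). Objects touching field borders are kept — the consensus stage
owns border handling.

Features per object: area; perimeter by the Crofton 4-direction
estimator (raw boundary-pixel counts overestimate smooth contours by
~27%); eccentricity from second central moments; per-channel integrated
and mean intensity; texture as the within-object intensity standard
deviation (deliberately the simplest texture summary). The maximum edge
distance of a colony is the maximum of its per-component interior
distance transform — computed per labelled component so distances never
bleed across adjacent colonies.

## Colony context

Distance from edge is the per-colony interior distance transform
evaluated at the cell centroid, exactly 0 for centroids outside every
colony (such cells are "peripheral", colony id 0). Layers: distance 0 →
periphery; distance in ((k−1)·d, k·d] → Layer k for k ≤ 3; beyond →
interior. The layer width d defaults to the median equivalent diameter
of the segmented nuclei of the sample and can be configured; thresholded
footprints underestimate the true diameter somewhat, so a configured
nominal diameter is preferable when it is known. Colony size classes cut
the maximum edge distance at 150 and 300 µm with both boundaries in the
medium class (the boundaries are measure-zero). Density windows tile
each colony's centroid bounding box (partial edge windows kept, the
closed maximum bound attached to the last row/column); class edges
default to the tertiles of window counts over the sample and can be
overridden. Equal-count distance bins are empirical quantiles; duplicate
edges under heavy ties are collapsed with a warning, and an all-ties
input degenerates to a single bin rather than erroring.

## Gating and bootstrap

Each two-mode fit is a 2-component Gaussian mixture on log intensity,
deterministically initialised at data quantiles (25th/75th), accepted
only when Ashman's D = |µ₁−µ₀| / sqrt((σ₀²+σ₁²)/2) ≥ 2 — otherwise the
channel is reported as unimodal by name. Thresholds sit at the antimode
(equal weighted-density crossing between the means). The EdU threshold
is fitted first and the 2N/4N DNA mixture is then fitted on EdU-low
cells only: S-phase cells hold intermediate DNA content and would bias
both centers (by ~7% at a 30% S fraction). Gate widths are ±3 component
log-SDs around each DNA mode (configurable). Classification precedence
is S > M > G1/G2: EdU incorporation trumps DNA content, and pH3 resolves
M within the 4N population; DNA-gate ambiguity resolves to the nearer
mode on the log scale. All gate parameters are scale-equivariant, so
classification is invariant under global intensity rescaling when gates
are refit.

Bin frequencies use multinomial resampling of the observed category
counts (equivalent to resampling labels with replacement), B = 1000 by
default, with plain central percentile CIs — not BCa — at the stated
level, clipped to bracket the point estimate. A single seed governs all
resampling. Empirical coverage of the 95% CI over simulated bins of
1500 cells is within 95 ± 2.5% (the acceptance script recomputes this).

## smFISH

Preprocessing subtracts a per-plane morphological opening (the opening
estimates smooth out-of-focus background, so the structuring element
must be *larger* than a spot — a warning fires when `open_radius` is
below ~2× the LoG σ, where the top-hat would erase spots) and applies a
negated Laplacian of Gaussian so spots become positive peaks; the axial
σ is scaled by the voxel anisotropy. Candidates are 26-connected local
maxima above a permissive floor (median + 2 SD of the filtered stack —
low, so that near-threshold candidates survive for the equalization
stage to arbitrate).

The spot statistic multiplies the mean magnitude of the negative
eigenvalues of the 3 × 3 second-difference Hessian (z, y, x) of the
smoothed raw stack at the peak by the peak intensity above the local
background (median-free shell mean of a surrounding box). It is
increasing in both sharpness and brightness and scales as c² under raw
intensity scaling c; at SNR ≥ 4 on synthetic stacks, spots and noise
candidates separate with ROC AUC ≥ 0.99.

Threshold equalization minimises the margin-count error E(S) over the
per-field thresholds. Margins are the physically shared strips of width
equal to the grid overlap — only shared content is compared; each
adjacent pair contributes one right↔left or bottom↔top term (counting
both directions would scale E by 2 without moving the minimiser). The
initial estimate S0 thresholds the pooled candidate statistics of all
fields: the antimode of a two-component mixture on the log statistics
(high component seeded in the far right tail, since noise candidates
far outnumber spots), falling back to Otsu when the pooled distribution
is not bimodal. E is piecewise-constant in each s_xy, so cyclic
coordinate descent evaluates only the breakpoints (each field's own
margin-candidate statistics, plus S0 and a value above the maximum),
performing exact per-coordinate minimisation; ties resolve to the
threshold closest to S0 on the log scale (then the smaller), keeping
local adjustments anchored to the global estimate rather than drifting
into the noise floor. The descent stops when a sweep changes nothing
(≤ 50 sweeps) and never ends above E(S0).

Cell territories expand nucleus labels outward by a watershed on the
distance to the nearest nucleus, constrained to the colony mask (Otsu
on the maximum projection of the diffuse RNA background staining, holes
filled, small components dropped); boundary points equidistant between
two nuclei fall to the watershed line, and exact ties resolve to the
lower label. Spots outside the mask stay unassigned. Duplicate
detections of margin spots are merged greedily from the highest
statistic outward within a 2-px region-coordinate radius.

## Synthetic generator

The generator emulates: clustered colonies as smoothed-noise blobs
(low-pass-filtered Gaussian noise plus a radial ramp, thresholded —
generally non-convex, so distance-transform code faces realistic
masks); nuclei as anisotropic 2-D Gaussians clipped at 2σ with diameter
≈ 12 µm (typical hES nucleus scale, log-normal spread, CV 10%);
DNA-stain amplitude proportional to DNA content (G1 = 1, G2/M = 2, S
uniform in between); bimodal EdU/pH3/marker intensities with log-normal
within-mode spread; optional phase-probability overrides for the
periphery and the outermost layer (to plant spatial enrichment) and a
marker-negative fraction that may differ at the periphery; per-field
gain/background effects; Poisson shot noise plus Gaussian read noise
applied after gain, as in a CCD. smFISH stacks render spots as 3-D
Gaussian point sources (σ_xy = 1.3 px, σ_z = 1.6 px; widths below 1 px
are rejected as unresolvable) with log-normal amplitudes — producing the
hard near-threshold population the equalization method exists for — a
diffuse in-colony background for mask generation, and optional smooth
across-region or per-field gain gradients. Cell placement is hard-core
(default minimum separation 0.75 diameters, relaxed if a colony is too
crowded to honour the requested count).

What the generator does *not* emulate: realistic point-spread-function
aberrations, chromatic shifts, stage drift or registration error,
cytoplasm or membrane stains, debris and dead cells, illumination
vignetting within a field, and near-confluent packing (the regime where
real nucleus segmentation is hardest). Passing tests therefore establish
the correctness of the algorithms under their stated assumptions — not
that segmentation accuracy or spot recall transfer to arbitrary real
samples.

Problem sizes used in the test and acceptance runs (a few hundred cells
in 2–5 colonies, 3 × 3 field grids, 100–1000 spots in 12–20-plane
stacks) were chosen to exercise every code path at desk scale; all
statistical checks state their tolerances explicitly in the tests.

## Known limitations

- The overlap-consensus rule assumes the stage error is well below a
  cell radius; there is no sub-pixel registration fallback.
- Density windows tile per-colony bounding boxes (window positions are
  colony-relative); tiling the whole region instead would change window
  boundaries for cells of adjacent colonies.
- The bootstrap treats cells as exchangeable within a bin; spatial
  autocorrelation within colonies is not modelled.
- Threshold equalization matches margin *counts*, not margin *identity*:
  with very few margin spots it can match Poisson fluctuations instead
  of systematic gain differences; the S0-anchored tie-break and the
  1-norm option mitigate but do not remove this.
- 4-way corner correspondences reuse the pairwise larger-area rule
  transitively; no global optimisation over correspondence groups is
  attempted.
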