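# Methods

`dermoseg` analyzes single-lesion dermoscopic (or plain digital) skin
images: it localizes the lesion, segments it in two passes built on
minimum-spanning-tree block weights and a fuzzy-number threshold, and
extracts the clinical ABCD quantities (asymmetry, border, color,
diameter) plus a physically scaled size. This note records the model,
its assumptions, the tunable parameters, and the design choices made
where the method description left matters open.

## Two-pass graph segmentation

**Block weights.** The grayscale image is tiled into non-overlapping
4×4 blocks (raster order; right/bottom remainders are zero-padded, and
padded pixels are excluded from any output mask). Each block's value
grid is read as the adjacency matrix of a complete graph on 4 vertices:
entry (i, j) is the weight of the directed edge i→j, diagonal entries
are self-loops and discarded, and the (i, j)/(j, i) pair — a multi-edge
— is collapsed to its minimum. A spanning tree is grown greedily from
vertex 0, always adding the cheapest edge that leaves the connected set
without closing a circuit (ties broken on the lexicographically
smallest vertex pair, for determinism). On a complete graph this greedy
growth is Prim's algorithm, so the block weight

    W = e₁ + e₂ + e₃

is the global minimum spanning-tree weight; the test suite verifies
this against exhaustive enumeration of all 16 spanning trees of K₄.
Because the MST takes minimum edges, W tracks the *dark* order
statistics of a block: homogeneous dark (lesion) blocks score low,
bright skin blocks score high, and mixed boundary blocks score close to
the lesion side.

**Pass I.** Blocks with W ≤ T are selected. T has no prescribed value;
the default is the mean of all block weights of the analyzed region —
scale-free, and on a region that contains both lesion and skin it falls
between the two weight modes. T is overridable in the configuration.

**Pass II.** The selected blocks' weights define an L-type fuzzy number
with left shoulder α = median(W selected) and support end
β = max(W selected): membership 1 up to α, a linear ramp down, 0 at β.
Defuzzification by the area-approximation method (rectangle α·1 plus
triangle (β−α)/2) gives the dynamic threshold

    D = (α + β) / 2 ≤ T,

and only blocks with W ≤ D survive. Pass II is therefore a *subset* of
pass I by construction. As printed, the L-type membership definition is
internally inconsistent (it assigns 1 above the shoulder and a rising
ramp on the support); we implement the decreasing reading — the only
one whose areas match the defuzzification derivation.

**Assumption and known limitation.** Pass II treats the upper tail of
the selected-weight distribution as contamination that the loose pass-I
threshold let through. That holds when the lesion's weights are
unimodal (single tone, or a dominant bright tone). When a lesion is
strongly *bimodal* with the darker tone in the majority — flat,
equal-area color fields of very different brightness — the median sits
in the dark mode, D lands below the bright lesion mode, and pass II
removes genuine lesion area. On the synthetic suite this is visible on
multi-tone phantoms with dark-dominant sector fills; single-tone and
bright-dominant phantoms consistently gain Jaccard from pass II. Real
lesions mix tones with gradual transitions, which moves every block's W
toward the dark side and defuses the failure mode, but the limitation
is intrinsic to the median/max construction.

**Pipeline ordering.** Hair removal runs first, then histogram
equalization. The ROI proposal and the segmenter consume the
hair-repaired, *pre-equalization* grayscale by default
(`segment_on_equalized` restores the literal chronology): equalization
stretches background noise so strongly that skin-block weights collapse
into the lesion range (measured on phantoms: the 5th percentile of skin
block weights fell from ≈540 to ≈143 after equalization), destroying
the separation both thresholds depend on. ROI crops are aligned
outward to the block grid so zero-padded partial blocks (whose W ≈ 0
would always be selected) cannot occur inside the frame. The final
mask is hole-filled, and a mask covering more than 90% of the frame is
reported as "no lesion" — a featureless image selects every block
(W = T everywhere), and "everything is lesion" is no lesion at all.

## Preprocessing

**Hair removal** follows the classic razor recipe. A grey morphological
closing with linear structuring elements of length 9 px at 0°, 45°,
90° and 135° (maximum over orientations) fills thin dark structures;
the closing residual is thresholded at mean + 2·std of the residual
image; candidate components must be at least 15 px long (major axis)
and at most 5 px in mean width (area/length) — wide dark blobs, i.e.
the lesion, are rejected by the thickness test. Flagged pixels are
replaced by the average of the horizontal and vertical linear
interpolants from the nearest clean pixels (fully masked lines fall
back to the nearest clean pixel), then a 5 px median filter is applied
inside the dilated mask only. Unflagged pixels outside that region are
returned bit-identical, and an all-true mask is an error.

**Histogram equalization** is the standard cumulative-distribution
remap on the luminance channel; chroma is preserved by scaling each
pixel's channels by the luminance ratio, so hue and saturation — the
inputs of color classification — are not corrupted. The mapping is
monotone, hence intensity rank order is preserved; constant images are
returned unchanged.

## ROI proposal

The detector stage is a pluggable interface with two providers: a
ground-truth box file, and an untrained intensity proposer (Otsu
threshold, dark side as foreground, largest connected component's
bounding box; confidence = the component's darkness contrast
normalized to [0, 1]). The proposer returns the tight component box;
crop generosity (default 15% expansion) is applied by the pipeline at
crop time. Box IOU uses center-format boxes converted to corners; a
detection is accepted only when IOU *strictly* exceeds the 0.80
threshold.

## ABCD feature extraction

All geometry runs on the ordered outer boundary of the largest mask
component, traced with Moore-neighbor tracing (Jacob's stopping
criterion), orientation normalized to a positive shoelace sum.
Coordinates are (x = column, y = row), 0-based, y downward; angles in
degrees from the horizontal axis.

**Center.** The iterated-midpoint "resultant" center — c₁ = p₁,
c_k = (c_{k−1} + p_k)/2, closed form weighting point i by
2^{i−2}/2^{n−1} — is computed over all mask pixels in raster order
(a contour-ordered mode is also available) and reported. Because the
weights decay geometrically, the resultant is dominated by the last few
points of whatever ordering is used, and for raster order it lands near
the bottom boundary of any large region. Probing asymmetry from such a
point would flag every shape, including perfect disks, as asymmetric;
the pipeline therefore probes from the mask centroid — the
order-independent center the construction plainly aims at — while the
resultant value remains available for inspection. The closed-form /
iteration equivalence is verified to 1e-9 for n ≤ 30.

**Asymmetry / border.** Lines y = tan(a)(x − x₀) + y₀ are probed at
a ∈ {0°, 5°, …, 175°} (the 90° probe uses x = x₀). On each side of the
center, the boundary point nearest the ideal line within 1.5 px
(perpendicular distance; ties to the outermost point) is the hit, and
dk1, dk2 are the Euclidean hit–center distances. A probe is *unequal*
when |dk1 − dk2| > 0.1·max(dk1, dk2); the lesion is asymmetric (and its
border irregular) when more than half the probes are unequal — the
majority reading of "in maximum cases". Centrally symmetric shapes
(disks, centered ellipses and squares) are symmetric under this rule at
any angle step.

**Color.** Lesion pixels are converted to HSV (H in degrees [0, 360),
S and V in percent) and matched against six inclusive reference boxes
(light brown, dark brown, tan black, blue gray, red, white), each
stated by two corner triples whose per-channel min/max define the box.
Three robustness rules, all config-exposed, make the degenerate boxes
usable on 8-bit, noisy rasters:

* each box is expanded by ±1 (degree / percent point) per channel to
  absorb 8-bit quantization;
* a 5×5 masked median prefilter runs before the HSV conversion (the
  background is blanked first, so pixels outside the mask can never
  influence a label) — at dark values a ±4-count RGB perturbation
  swings hue by tens of degrees;
* for boxes whose saturation maximum is ≤ 5% (blue gray, white), pixels
  with S < 5% match any hue: quantization collapses near-gray hues to
  0, so those boxes would otherwise be empty.

The label grid is zero-padded by one pixel and pruned by the "plus"
operation: labeled pixels on a cluster border line are always kept;
interior pixels are suppressed when their label does not exceed the
mean of their 4-neighborhood. A class enters the reported color set
when at least 20 of its pixels survive, guarding against isolated
noise hits.

**Diameter and area.** The diameter is the complete all-pairs maximum
distance between boundary points (ties to the smallest indices),
verified exactly against brute force; the staged-maxima formulation
that stops at n/2 can miss pairs with both indices in the second half,
so the complete search is used. The area is the orientation-independent
shoelace sum; the *reported* lesion area adds the half-boundary lattice
correction B/2 + 1 (Pick's theorem), making it an estimate of the
enclosed pixel count — without it, a traced disk of radius r
underestimates its area by ≈ 1/r (3% at r = 30).

**Physical scale.** With focal length f (mm), object distance u (mm)
and pixel pitch p (mm/px), the magnification from image plane to object
plane is (u + f)/f, so L = d·p·(u+f)/f and A = Δ·p²·((u+f)/f)². The
printed formula is garbled; this is the reading consistent with the
squared area factor and with L growing with u. Without a pixel pitch
the results are flagged `"units"` and left in pixels.

## Evaluation metrics

Pixelwise confusion counts (foreground = lesion) feed
Sen = TP/(TP+FN), Spe = TN/(TN+FP), Dic = 2TP/(2TP+FP+FN),
Jac = TP/(TP+FN+FP), Acc = (TP+TN)/total; mask IOU is computed
set-theoretically and equals Jac by identity (both identities —
Dic = 2·Jac/(1+Jac) included — are property-tested). Metrics with zero
denominators are reported as explicit `None`, never silently 0, so
empty-mask edge cases stay visible in batch reports.

## Synthetic phantoms

The generator emulates the study population at desk scale: a skin-toned
canvas (RGB 224/172/150), one darker lesion — disk, centered ellipse,
notched disk (wedge bite, default fraction 0.35 of the full angle so
the majority probe rule has margin), or radial blob
r(θ) = R(1 + Σ a_k cos(kθ + φ_k)) — painted in angular sectors from the
reference palette (box-center HSV converted to RGB), optional thin dark
hair strokes (width ≈ 2 px, spanning the frame), and clipped Gaussian
pixel noise (sd 4 gray levels, chosen to keep lesion and skin block
weights separable while exercising the classifiers). Everything is
deterministic given the spec seed.

Ground truth is analytic, not raster: disk/ellipse diameter and area in
closed form; notched-disk area πR²(1−q) with the centroid shift of the
removed wedge computed exactly; blob diameter/area by dense quadrature
of the generating radial function. Blob asymmetry truth applies the
same majority rule to r(θ) vs r(θ+π) analytically — even harmonics give
symmetric shapes, odd harmonics asymmetric ones, with amplitudes keeping
the unequal-probe fraction well away from the 0.5 decision boundary.
The stratified suite cycles shapes and color compositions (≥25%
asymmetric, ≥25% multi-color, hairy/hairless mix); suite lesion radii
are 26–38 px on a 160×160 canvas.

What the phantoms do **not** emulate: gradual tone transitions and
pigment networks (sector fills are flat), ruler/ink/vignetting
artifacts, specular reflection, the white color class inside lesions
(V ≈ 96% is brighter than the surrounding skin, so no intensity-based
segmenter would retain it; white is exercised in direct classifier
tests instead), and genuinely out-of-focus capture. Passing phantom
tests therefore demonstrates correct mechanics and parameter recovery
under controlled conditions, not clinical-grade performance on real
dermoscopy.

## Problem sizes and numerical choices

Property suites run 10,000 random blocks against the exhaustive MST
oracle, 1,000 polygons/point sets against the geometry oracles, 10,000
random confusion tables against the metric identities, and a 50-phantom
seeded suite for recovery and segmentation checks — sizes chosen to
exercise the combinatorics thoroughly while keeping a desk-scale run.
Recovery checks run the ABCD extractor on ground-truth masks, isolating
extractor error from segmentation error, which is assessed separately.
Floating-point tolerances: closed-form equivalences at 1e-9; exact
integer/count comparisons wherever the quantity is discrete. Median of
an even-length list is the mean of the middle two. Degenerate fuzzy
numbers (α = β) defuzzify to α. Empty masks, empty selections,
all-true hair masks and out-of-range parameters raise errors rather
than returning sentinel values.
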