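# Methods

`veinmatch` implements a finger-vein verification pipeline built from three
matchers — a curvature-based vein *shape* template, an 8-direction vein
*orientation* template, and SIFT keypoint descriptors — combined by
score-level fusion, together with a synthetic phantom generator that makes
the whole pipeline testable without access to any vein database.

## Difference-curvature vein extraction

A vessel in a near-infrared transmission image is a dark valley running
along the finger.  For a pixel and a direction θ, the cross-sectional
profile P(z) is sampled by bilinear interpolation at unit arc-length
spacing, and its curvature at the pixel is

    K = |P″| / (1 + P′²)^{3/2}.

Derivatives are estimated by central differences *spanning the profile
half-width r* (samples at z = −r, 0, +r; exact for quadratics):

    P′ = (P(r) − P(−r)) / 2r,    P″ = (P(r) − 2P(0) + P(−r)) / r².

The span matters.  A unit-step stencil measures curvature at the pixel
scale, where a smooth vessel valley decomposes into a weak core, zero
rings at the profile's inflections, and shoulder responses of ≈ 0.45× the
core strength: no global threshold can then recover the vessel band.  At
the vessel scale (r = 4 by default, above the typical vessel half-width of
2–3 px) the response is a single band centred on the vessel.

Directions are quantized to eight angles θ_j = (j−1)π/8 grouped into
perpendicular pairs G_j = {j, j+4}.  The per-group curvature difference
ΔK_j (K_j − K_{j±4}) is antisymmetric between partners, so the per-pixel
enhancement value D_max = max_j ΔK_j is nonnegative; it is large on
line-like structure and small both on flat regions and on isotropic blobs
or noise, whose orthogonal curvatures cancel.  Binarizing D_max with a
global threshold yields the vein shape template; the maximizing index
j_max ∈ 1..8 (ties to the smallest j) is the orientation code, which names
the *cross-sectional* direction — perpendicular to the vessel tangent.
Codes are restricted to the binarized support (0 = background), since an
orientation is only meaningful where a vein was detected.

**Threshold selection.**  The enhancement histogram is strongly
unbalanced: a large near-zero background class against a small,
wide-spread vessel class.  Otsu's between-class-variance rule tends to
land below the vessel band's shoulder level under these conditions, so
the default selector is Yen's maximum-correlation (entropy) criterion,
with Otsu and fixed numeric thresholds available via `threshold` in the
config.  On the default phantoms, Yen raises the mean segmentation Dice
from ≈ 0.72 to ≈ 0.75.

## Keypoint matching

SIFT keypoints (scale-space DoG extrema with 128-element gradient
histograms; `skimage.feature.SIFT` with its standard parameters) are
detected on the smoothed grayscale image, not on the templates.  Every
gallery keypoint is paired with its Euclidean-nearest probe descriptor.
Because vein images are smooth and low-contrast, Lowe's second-nearest
ratio test separates little (it is provided only as a baseline,
`lowe_ratio_filter`, c = 0.8 by convention); instead, the pairs are
ranked by the geometric distance between their image positions and the
k = min(T, m) closest pairs are kept (T = 20), discarding the rest as
mismatches.  The SIFT score of a comparison is the mean descriptor
distance over the k retained pairs; lower means more similar.

## Sub-region template matching

The retained matches anchor k local windows on the shape and orientation
templates: a larger gallery window and a smaller probe window per match
(defaults 120×60 / 110×50 px for shape and 60×40 / 50×30 px for
orientation, width × height), centred on the matched keypoint positions
and zero-padded at template borders.  Each probe window slides over every
integer offset inside its gallery window; its score Ψ is the minimum
mismatch fraction over offsets, where a pixel mismatches if the binary
shape values differ, or if the orientation codes differ (two background
zeros agree; `ignore_background=True` instead drops them from the
denominator).  The comparison's template score is the mean of the k
values of Ψ, in [0, 1].  Keypoint anchoring absorbs global translation
and rotation; the offset search absorbs residual local shifts.

## Score-level fusion and evaluation

Each comparison yields a (sift, shape, orientation) distance vector.
Scores are z-score normalized — population mean and standard deviation
estimated on training data only — and fused either by a weighted sum
(weights nonnegative, summing to 1) or by an RBF-kernel C-SVC
(γ = 0.006, C = 1.2; genuine labelled +1, imposter −1) whose signed
decision value is negated so that lower always means more genuine.

Verification experiments enumerate all unordered within-class sample
pairs as genuine comparisons and, for every unordered class pair, all
s × s crossings of a designated s-sample subset as imposter comparisons.
A comparison is accepted when its score ≤ threshold; sweeping the
threshold over all observed scores gives FAR and FRR, and the EER is
interpolated between the two consecutive (FAR, FRR) pairs bracketing the
crossing — interpolating in rate space rather than threshold space makes
the EER exactly invariant under monotone transforms of the scores.
`run_experiment` repeats a half/half genuine+imposter split 20 times;
per repeat it fits the normalization, selects the weighted-sum weights on
the training half (exhaustive simplex grid, step 0.05, minimizing
training EER — fixed weights, e.g. the reference 0.1/0.7/0.2, can be
pinned via config) and trains the SVC, then reports mean ± sd of EER and
of GAR at a configurable FAR for each single feature and both fusers.

## The phantom generator

Each phantom models a 221×83 px cropped NIR finger image (the reference
crop size): background level 0.7 with a 0.1 illumination gradient across
the width, a smooth tissue-texture field (sd 0.05, correlation length
6 px — real tissue texture is what gives SIFT its keypoints), 4 vessels,
and white sensor noise (sd 0.02).  Vessels are cubic-spline centerlines
running lengthwise, one per horizontal band (veins in these crops are
roughly parallel and separated), with gentle meander (knot sd 2% of
height).  The cross-section is a Gaussian shadow whose depth scales with
vessel width (Beer–Lambert absorption through a wider blood column) and
whose sigma is `scatter × width/2` with scatter = 1.1 (tissue scattering
spreads the shadow slightly beyond the vessel).  Widths are drawn from
4–6 px.  Ground truth is exact: the vessel mask marks pixels within
half-width of a centerline, and every vessel pixel carries the centerline
tangent angle in [0, π).

A genuine pair moves the *geometry*, not the pixels: the centerlines are
transformed by a rigid motion plus a smooth random elastic displacement
field and re-rendered sharply at the new pose; the texture is warped
along with the finger, the illumination gradient stays fixed to the
sensor, and fresh sensor noise is drawn.  Re-rendering avoids the
interpolation blur of image warping and keeps the ground truth exact.
Dataset defaults model a guided capture device: shifts up to ±4 px, roll
up to ±0.05 rad (≈3°; a guide slot constrains finger rotation far below
the π/8 tolerance of the orientation coding, and rotations much larger
than ~5° would defeat the ±5 px translation search of the sub-region
matcher), elastic amplitude 1.5 px at correlation length 10 px.

What the phantoms do *not* model: photon scattering blur and
depth-dependent defocus, vessel branching and crossings, bones and joint
shadows, pressure-dependent vein collapse, and sensor fixed-pattern
artifacts.  Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the method (feature separation, the benefit of
fusion, segmentation fidelity), not the absolute error rates reachable on
real finger-vein databases.

## Numerical choices and edge cases

- Profiles and directional samples use bilinear interpolation with
  reflected coordinates; smoothing uses reflect padding (avoids dark
  borders that would masquerade as vessels).
- Eq. argmax ties (orientation codes) break to the smallest j; ties in
  the k-th geometric distance break by smaller descriptor distance, then
  input order.
- A comparison in which either image yields no keypoints raises a
  no-match condition; batch scoring maps it to a worst-case score vector
  (sift 10⁴, shape 1, orientation 1).
- σ in the z-score is the population standard deviation (ddof = 0;
  configurable).
- A constant enhancement map binarizes to an empty mask rather than
  failing in the histogram threshold selector.
- All randomness flows from integer seeds through `numpy` Generators;
  fixed seeds reproduce phantoms bit-for-bit.

## Problem sizes

The bundled end-to-end experiment uses 20 classes × 6 samples
(120 images, 300 genuine and 760 imposter comparisons with a 2-sample
imposter subset) and 20 repeated splits — small enough to run in about a
minute on one CPU while leaving every rate estimate comfortably away from
its acceptance margin.  The protocol-arithmetic checks enumerate the full
reference protocols (up to 426 classes, 2.26 million imposter pairs)
explicitly.
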