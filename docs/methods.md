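# Methods

This note records the models implemented in `mritumor`, the choices made
where the design was genuinely open, and what the synthetic phantoms do
and do not establish about real MRI data.

## Image model and normalization

All stages operate on a 2-D real-valued image normalized to [0, 1] by
min-max at read time (`GrayImage`). The downstream statistics (deviation
shifts, intensity clustering, gray-level binning) are scale-sensitive,
so a single declared range keeps their parameters meaningful across
8-bit PNGs, 16-bit TIFFs, NIfTI and DICOM slices. A constant image
normalizes to all zeros rather than NaN, so degenerate inputs flow
through the pipeline with defined behavior. Quantization to W levels
uses half-open equal-width bins, `level = min(floor(p·W), W−1)`; the
top-of-range pixel clamps into the last bin.

## Contrast enhancement

The transform adds the image's mean absolute deviation (AD) and
subtracts a third-moment statistic (SK):

    IF = X + AD − SK,
    AD = (1/n) Σ |x_i − x̄|,
    SK = Σ (x_i − x̄)³ / ((n−1) s³),  s² = Σ(x_i − x̄)²/(n−1).

Both are global scalars, so the un-rescaled transform is a pure shift
that preserves every pairwise intensity difference; the default then
min-max rescales to [0, 1]. Two open points are resolved as follows and
exposed as configuration rather than hard-coded:

* SK is a skewness-type (third-power) statistic even though it is
  sometimes labeled a kurtosis; `sk_form="third_moment"` is the default
  and `"third_moment_over_s"` applies an additional 1/s prefactor.
* AD/SK are global by default; `window=w` computes both in sliding w×w
  windows for a locally adaptive variant. The windowed statistics use a
  separable-filter approximation (each pixel's deviation is taken from
  its own window mean) and treat windows with sd ≤ 1e−6 as constant, a
  guard against catastrophic-cancellation noise in flat regions.
* Constant images are fixed points (AD = SK = 0, rescale skipped).

## Fuzzy c-means segmentation

Standard FCM on pixel intensities with fuzzifier m (default 2, the
universal choice; any m > 1 is accepted):

    s_kl = 1 / Σ_j (d_kl/d_jl)^(2/(m−1)),  d_kl = |x_l − T_k|,
    T_k  = Σ_l s_kl^m x_l / Σ_l s_kl^m.

Update schedule: membership from the current centroids → (optional
spatial reweighting) → centroid update; convergence when the largest
elementwise membership change is ≤ ε (default 1e−3), capped at
`max_iter` (default 200, returned with `converged=False` and a warning
rather than an exception). The objective trace records
½ Σ s^m (x−T)² once per iteration; in plain mode it is provably
non-increasing and is asserted as such in the tests. Pixels at zero
distance from one or more centroids take membership split equally among
those centroids; coincident centroids therefore share a pixel's
membership instead of dividing by zero. Defuzzification is per-pixel
argmax with ties to the lower cluster index.

**Spatial regularization.** Each iteration, memberships are reweighted
by neighborhood agreement: s′_kl ∝ s_kl^p · h_kl^q with h_kl the mean
membership of cluster k over an odd window (default 3×3, reflect
boundary, p = q = 1), then renormalized per pixel. This is the standard
membership-neighborhood construction for spatial FCM; it pulls isolated
noisy pixels toward the label of their surroundings. Exact 0/1
memberships are fixed points of the multiplicative form — in practice
FCM memberships are never exactly crisp for off-centroid pixels, which
is where the regularizer acts.

**Initialization.** Three modes:

* `histogram` (default): a W×W co-occurrence matrix I of quantized
  levels over the 4-neighborhood is accumulated; a coarse feature map
  (local maximum of the image weighted by each pixel's level frequency)
  is computed; initial centroids are the midpoints of the c most
  frequent levels of I's marginal. The coarse map and matrix are kept in
  `InitContext` for inspection. This mode is faithful to the
  intensity-level bookkeeping it derives from, but it is fragile when a
  tissue intensity sits exactly on a quantization bin edge (the mode's
  mass splits across two bins and can drop out of the top-c ranking).
* `kmeans`: centers of a seeded hard K-means on the intensities
  (n_init = 10). Robust to the bin-edge pathology; the pipeline default.
* `random`: seeded uniform draws over the intensity range, the fully
  initialization-free variant.

Explicit `init_centroids` override all modes; this is also how the
test suite pins both the implementation and its brute-force oracle to
identical starting points when checking 1e−6 agreement.

**Tumor mask.** The cluster with the highest centroid is taken as tumor
(tumors are hyperintense on the targeted sequences); a warning fires if
the mask covers more than half the image. The alternative rule takes the
largest connected component outside the lowest-centroid cluster. Both
are explicit and overridable since the choice is a reading of the data,
not part of the clustering.

## Texture and shape features

First-order statistics come from the W-level histogram of the region
(SD, skewness (1/S³)Σ(k−k̄)³p(k), kurtosis (1/S⁴)Σ(k−k̄)⁴p(k) — plain,
not excess — energy Σp², entropy −Σp log₂ p with 0·log 0 := 0; skewness
and kurtosis are 0 when S = 0). GLCM features use the symmetric
normalized co-occurrence matrix averaged over the four distance-1
Haralick directions: contrast ΣP(k,l)(k−l)², homogeneity
ΣP/(1+(k−l)²), energy ΣP², correlation Σ P(k−M)(l−M)/S4² with M, S4 the
marginal mean and sd (0 when S4 = 0). Busyness and strength follow the
standard NGTDM definitions: per level i, s_i sums |i − neighborhood
mean| (window 3, centre excluded, truncated at borders);
busyness = Σ p_i s_i / Σ|i·p_i − j·p_j| and
strength = Σ(p_i+p_j)(i−j)² / Σ s_i over present levels, both 0 when the
denominator vanishes. Shape descriptors (area, perimeter, eccentricity,
solidity) come from the largest connected component of the mask via
scikit-image regionprops.

Two composition choices matter in practice:

* **ROI-local binning.** `extract_features` min-max normalizes the
  intensities over the region of interest before quantizing, the common
  radiomics convention. Binning a bright tumor ROI against the global
  range would put nearly all its pixels into the top bin, making the
  texture features a knife-edge function of which stray rim pixels cross
  a bin boundary; ROI-local binning measures contrast *within* the
  region and is stable.
* **Empty masks.** With no mask (or an empty one) the features are
  computed over the whole image and the shape descriptors are 0 —
  "no region to describe" is itself informative for the no-tumor class.

W defaults to 8 levels (a common texture default), offsets to the four
distance-1 directions, symmetric and averaged after normalization. The
module contains no randomness.

## Entropy-based feature selection

Each column's entropy comes from a 10-bin equal-width histogram of its
min-max-normalized values. Note a consequence of that normalization:
entropy is scale-free, so a column that is "almost constant" but carries
smooth small-amplitude variation still has high entropy; only columns
concentrated in few bins after normalization (including exactly constant
ones, entropy 0) score low.

Ranking is greedy: seed with the max-entropy column; score every
remaining candidate as score = min(d_curr, d_prev) · entropy, with
d_curr the Euclidean distance between z-scored columns to the most
recently ranked feature and d_prev the minimum distance to all earlier
ranked features; rank the argmax and repeat. The min-over-all-previous
form makes an exact duplicate of *anything* already ranked score 0
permanently — with a window of only the last two ranked columns, a
duplicate could regain a positive score later, which would defeat the
redundancy intent. The threshold is either the score of the single
most-concentrated (lowest-entropy) feature (`max_prob`, default) or a
quantile of all scores; kept = the seed plus every ranked feature whose
score strictly exceeds the threshold, in ranking order. The strict
inequality is what guarantees that zero-scored duplicates are dropped
even at threshold 0. Fitting selection on the training split only is the
pipeline default (leakage-safe).

## Extreme learning machine

Features are min-max scaled with the training scaler; input weights and
biases are drawn once uniformly from [−1, 1] (seeded) and frozen; the
hidden representation uses a sigmoid by default (tanh/ReLU available);
output weights solve min‖Hα − O‖ for one-hot targets via
`numpy.linalg.lstsq` (ridge > 0 switches to the regularized normal
equations). With H equal to the number of distinct samples and no
ridge, the square system is generically full-rank and the network
reproduces its targets to ~1e−9 — the "zero error" regime, asserted at
1e−6 in the tests. Decoding is argmax with ties to the first class;
classes are the sorted unique training labels. The library default
H = min(100, n−1) respects the hidden-nodes-below-sample-count rule; the
*pipeline* default is H = 40 with ridge 1e−3, because near-interpolating
hidden layers on feature tables of a few hundred rows generalize
measurably worse (high variance across weight draws). Models serialize
to a single JSON file.

## Evaluation

Confusion matrix with a fixed class order; accuracy, per-class
precision/recall/F1 and macro averages in percent (two decimals in the
serialized report); 0/0 ratios take the zero-division value (default 0)
with a warning. One-vs-rest accuracy per class is reported alongside the
overall accuracy since per-class "accuracy" is ambiguous in the
literature. Dice = 2|A∩B|/(|A|+|B|), with two empty masks defined as 1.

## Synthetic phantoms

Each phantom is an ellipse of three concentric tissue bands — CSF, gray
matter, white matter at intensities 0.25/0.55/0.80 on a 0.0 background —
with ±5% seeded jitter of the brain axes and centre. Tumors are
hyperintense (0.95) with class-specific geometry: glioma, an irregular
blob in the white matter whose boundary radius is modulated by random
sinusoids (roughness 0.35) with strong internal texture (amplitude 0.1);
meningioma, a smooth ellipse tangent to the brain surface (texture
0.02); pituitary, a small round blob (half the default 4% area target)
at the central inferior position; or no tumor. Noise is additive
Gaussian (default σ 0.02) or Rician √((x+ε₁)²+ε₂²), clipped to [0, 1].
One master seed fixes every sample of a dataset.

The defaults are chosen so that tissue intensities are separated by at
least ~7σ at the default noise — intensity clustering is then a genuine
but solvable recovery problem — and so that the class geometries encode
the qualitative radiology (infiltrative vs. surface-attached vs. small
sellar), making shape and texture features truly class-informative.

What the phantoms do **not** emulate: anatomy (gyri, ventricles,
asymmetry), bias fields, partial-volume averaging, scanner-dependent
contrast, tumor heterogeneity beyond a smooth modulation, and 3-D
structure. Passing the phantom suite therefore demonstrates the
*correctness* of every stage and the *sufficiency* of the feature set
for geometrically distinct classes — not clinical-grade performance on
real MRI, whose headline numbers depend on datasets and protocols
outside this package's scope.

## Problem sizes and numerical tolerances

The shipped test and acceptance workloads use 128×128 phantoms, 50
phantoms per segmentation-recovery condition, 200 phantoms (50 per
class, 80/20 stratified split) for end-to-end classification, 100 random
fixtures per oracle comparison and 10 seeds for the ELM interpolation
check — sizes at which every result is stable across seeds while the
whole suite runs in well under a minute per section on one CPU. Key
tolerances: membership column sums within 1e−9; oracle agreement 1e−6
(FCM) and 1e−10 (texture); ELM interpolation residual 1e−6; convergence
ε default 1e−3.

## Known limitations

* Clustering is on intensity alone; tissues with overlapping intensity
  distributions (real MRI) need features beyond the scalar pixel value.
* The histogram initialization inherits the bin-edge fragility noted
  above; prefer `init="kmeans"` on data whose modes are unknown.
* The greedy selection threshold (`max_prob`) always sacrifices the
  most-concentrated feature itself, even when that feature is
  discriminative; use `quantile` mode when in doubt.
* The multiplicative spatial regularizer cannot revive an exactly zero
  membership.
* Everything is 2-D; volumes must be sliced upstream.
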