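# Methods

This note records the model, the tunable parameters, the numerical choices,
what the synthetic scenes do and do not emulate, and the known limitations.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

Each pixel q of a 2-D MIP carries a latent binary label L_q (tree /
background) and an observed feature vector X_q ∈ ℝ⁸. The model assumes

* X_q | L_q = c  ~  N(μ_c, Σ_c), c ∈ {0, 1} — a single Gaussian per class,
  fit by maximum likelihood (covariance normalized by n, the MLE) on
  class-stratified random pixel samples;
* a flat prior P(L_q = 1) = 1/2 — estimating the tree prior from data is
  fragile because it depends on magnification and arbor size, so the
  posterior reduces to the density ratio g₁/(g₀+g₁);
* pixel-wise independence — no spatial regularization of the posterior;
  spatial coherence is recovered afterwards by morphology and Hough
  reinforcement.

The Gaussian assumption is a *noise* model: it is reasonable when the MR8
responses are perturbed by substantial acquisition noise, and degenerate in
the exact noiseless limit (see Limitations).

## Features

The Root Filter Set: for each of 3 anisotropic scales
(σ_long, σ_short) ∈ {(3,1), (6,2), (12,4)} and 6 orientations (0°…150° in
30° steps), an edge (first derivative across the bar axis) and a bar
(second derivative) kernel; plus an isotropic Gaussian and a
Laplacian-of-Gaussian, both σ = 10. Support 49×49. Oriented and LoG
kernels are mean-subtracted and L1-normalized; the Gaussian sums to 1.
These are the classic Leung–Malik parameters and are exposed in config
(`filter.support`, `filter.scales`, `filter.isotropic_sigma`).

MR8 pooling takes, per (type, scale), the per-pixel **maximum of absolute**
responses over the 6 orientations; the two isotropic responses keep their
sign. The result is invariant to exact grid rotations (90°/180°/270°
commute with the feature map to ≈1e-15) and approximately invariant at the
30° sampling in between.

Images are standardized to zero mean / unit variance before filtering, so
features are invariant to affine intensity rescaling. Per-pixel Weber-style
contrast normalization of feature vectors (texton-classification
convention) is available as `filter.weber_normalize` but **off** by
default: the Gaussian models are fit on raw MR8 responses.

Convolution uses reflective (mirror) boundary padding and a shared-FFT
implementation: the padded image is transformed once and multiplied with
each kernel's transform (verified against direct convolution to 1e-10).

## Threshold optimization

For a candidate threshold t, predictions are `posterior >= t` (closed lower
bound; ties count as tree). Confusion counts TP/FP/FN/TN are **pooled by
summation over all training images** before rates are formed, and the
selected threshold minimizes d_corner = √(FPR² + (1−TPR)²), equivalently
maximizes F = 2 − d_corner. Ties break toward the larger threshold (the
sparser labeling).

Counts are evaluated **exactly at every distinct score value** (two sorted
arrays and a vectorized rank lookup), not on a fixed grid: a subsampled
grid can miss the minimum-foreground-posterior threshold and therefore the
exact operating point in separable regimes. The stored curve is thinned to
`roc.n_thresholds` (default 512) quantile-spaced points for reporting, but
always retains the exact optimum and the sentinel endpoints (0,0) and
(1,1). In LOOCV the threshold selected on the training folds is applied
unchanged to the held-out image.

## Refinement

Pipeline order: opening → closing → Hough line reinforcement → user edits.

* Opening uses a **disk** (default radius 1). Tubular branches (a skeleton
  dilated by a disk) are exactly disk-open, so opening deletes speckle
  without touching intact limbs; a square opening would clip the rounded
  caps at branch tips.
* Closing uses a **square** of side 2r+1 (default r = 2). A square fits
  into the right-angle inner corners where branches meet, so closing
  bridges genuine gaps up to 2r px without depositing fillet pixels at
  every junction — a disk-shaped closing provably adds at least one
  background pixel per right-angle junction, which would contaminate
  every segmentation of a branched tree.
* Hough reinforcement: "strong" lines are probabilistic-Hough segments
  whose vote support reaches `hough.peak_fraction` (default 0.5) of the
  global standard-Hough accumulator maximum, with minimum length 25 px and
  gap tolerance 3 px; kept segments are stroked back into the mask at
  width 2 px (union, so reinforcement is monotone). These defaults were
  calibrated on the synthetic suite; on other data they are the first
  knobs to revisit.
* User edits are file-based add/remove masks applied last,
  `(mask ∨ add) ∧ ¬remove`; overlapping add/remove pixels are rejected.

Refinement reconnects structure and removes speckle; on scenes where the
coarse mask is already clean it can add a few false pixels (stroke ends,
bridged gaps), so its surface error is not guaranteed to undercut the
coarse mask's — its value is structural (connectivity), not raw pixel
error.

## Skeletonization

Guo–Hall two-subiteration hit-or-miss thinning, run one pass at a time to a
fixed point (iteration cap: the image diagonal). The soma mask, when given,
is subtracted before thinning and OR-ed back after — thinning a blob
produces spurious loops otherwise. Branch points in the summary are counted
as 8-connected clusters of skeleton pixels with ≥3 neighbors (a digital T
junction is a 3–4 pixel cluster but one branch point). Where two limbs run
closer than twice the stroke width the skeleton may still contain short
spurious loops or branches; the suite documents rather than forbids this.

## Synthetic scenes

Each scene renders: a gently undulating horizontal primary branch;
`n_secondary` equally spaced perpendicular secondaries with ±15% length
jitter, each capped by a tertiary cross-bar carrying short quaternary
teeth; a soma disk on the primary; the skeleton dilated by the branch
radius (default 2 px → ~5 px limbs) with junctions webbed by a closing at
branch-radius scale (real arbors show smooth fillets where branches meet;
this also makes the truth stable under tubular-scale smoothing); bright
isotropic Gaussian granules (default 40, radius 2–4 px, peak 0.80) placed
on and off the tree; a linear illumination ramp (default ±12.5%) in a
random direction; Gaussian blur (σ = 0.7 px); additive Gaussian noise;
clipping to [0, 1].

Default intensities — tree 0.55, background 0.30, noise SD 0.15 — put
plain intensity thresholding in a regime of substantial class overlap
(≈1.7σ separation), which is the regime the method exists for: granules
are *brighter* than the tree but texture-isotropic, so they confound the
intensity baseline and not the texture models. The defaults were fixed
once from this d′ arithmetic.

Not emulated: the confocal PSF and slice-wise noise aggregation of real
MIPs (noise here is i.i.d. additive), mutant/disorganized arbors, axons
and other neurites, intensity falloff along thin terminal branches.
Passing tests therefore demonstrate the machinery and its comparative
ordering under controlled conditions, not absolute performance on real
micrographs.

## Evaluation protocol

LOOCV over N scenes: for each fold, noise models and the sensitivity
threshold come from the pooled N−1 training images; the held-out image is
segmented, refined (no user edits), and scored. The intensity baseline
re-uses the identical ROC machinery with raw normalized intensity as the
score and is left unrefined — it represents traditional thresholding. Each
fold reports both the operating-point F-score and the best corner score of
the test image's own ROC (the per-image upper bound); summaries are
mean ± sd (n−1) across folds. Metrics are computed on the automatic
refined output, before any user edit.

Problem sizes in the shipped suite and acceptance script: 512² scenes for
the 12-fold LOOCV, 256² for single-scene checks, 192² for the 20-tree
connectivity sweep, 10⁶ pixels for the uniform-score ROC check. MR8 stacks
are computed once per image and shared across folds.

## Numerical choices

* Posterior in the log domain: one Cholesky factorization per class, then
  the logistic of the log-density difference — no under/overflow even at
  Mahalanobis distances of hundreds.
* Covariance ridge: default 1e-6·trace(Σ)/8 added to the diagonal, for
  invertibility when training data are (near-)degenerate; `model.ridge`
  overrides.
* Per-image sampling seeds mix the master seed with a CRC of the image id,
  so the training sample attaches to the image, not its position — fold
  composition and pair order cannot change it.
* Mask I/O is bit-exact (foreground stored as 255); float TIFF images
  round-trip to ≤1e-6, and float inputs already within [0, 1] are taken
  as-is rather than rescaled by their maximum.
* Degenerate inputs raise: constant images (zero variance, or a constant
  intensity pool in the baseline), masks missing a class, posteriors with
  no foreground or no background in the ROC pool.

## Known limitations

* **The noiseless limit is not exactly recoverable.** MR8 pools absolute
  oriented responses, discarding the inside/outside sign of the boundary;
  its only signed channels are σ = 10 isotropic filters. One-pixel-exact
  boundary localization is therefore not encoded in the features: on a
  corruption-free two-valued scene the pipeline converges to ≈98% yield at
  ≈2% surface error (boundary-hugging errors), and even nearest-neighbor
  classification on the exact feature vectors confuses a few percent of
  boundary pixels. The acceptance suite states the exact-identity claim
  and the corresponding test documents this gap; the plain intensity
  midpoint threshold, by contrast, does recover the noiseless truth
  exactly.
* Segmentations are intrinsically thicker than the underlying branches
  (filter support blurs the posterior), so closely spaced limbs can merge;
  skeletonization mitigates but can introduce loops there.
* The Gaussian class models are unimodal; arbors over strongly textured
  backgrounds (e.g. embryos, gut autofluorescence sheets) would need
  mixtures or locally adaptive models.
* Thresholds transfer across images only insofar as imaging conditions do;
  the LOOCV protocol measures exactly this transfer.
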