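# Methods

## The estimation problem

An individual *C. elegans* carrying a single-copy firefly-luciferase
reporter is photographed daily under a fluorescence microscope from the
first day of adulthood until death. Because the reporter protein is
metastable, it aggregates progressively as proteostasis declines with age,
appearing as bright, roughly circular spots. The task is to map one image
to the individual's **relative lifespan stage**: the fraction of its
realized lifespan already elapsed, discretized into 25 bins of 4 % each and
merged into six coarse groups (fine classes 1–5, 6–9, 10–13, 14–17, 18–21,
22–25). Staging by relative age rather than by chronological day rests on
the assumption that the modes of aggregation are shared across individuals
and only their rates differ, so a 10-day-lived and a 30-day-lived worm pass
through comparable physiological states at equal lifespan fractions.

The classifier is dual-path:

* **M1 (deep features)** — the image is average-pooled (at the
  instrument's native 6000 × 4000 resolution, by factor 10 to 600 × 400)
  and passed through a compound-scaled convolutional extractor with an
  attention block; global average pooling (GAP) of the final feature map
  yields the vector F1.
* **M2 (handcrafted aggregation features)** — the full-resolution image is
  histogram-equalized, low-pass filtered, high-pass filtered in the
  frequency domain, and swept by a multi-threshold blob detector; the
  sorted pairwise distances between detected spot centers, truncated to
  the 12 smallest and padded with a 5000 px sentinel, form the vector F2.
  Small distances mean tight clustering, i.e. advanced aggregation.

F1 and F2 are each standardized with training-set statistics, concatenated,
and classified by a dense softmax head (six classes) trained with
categorical cross-entropy, Adam, dropout, and early stopping.

## Staging rules

`fine = clamp(ceil(25 · day/lifespan), 1, 25)`. Bins are left-open /
right-closed: a relative age of exactly 32 % is class 8, and day 0 maps to
class 1. The worked check: day 5 of a 15-day lifespan is 33.3 %, class 9,
group 2. The train/test split is stratified per coarse group at 80/20 with
round-half-up on the train count; groups with fewer than two images go
entirely to train with a warning.

## Synthetic microscopy generator

The original image set is not public, so the package ships a seeded
generator that reproduces the statistical structure the method exploits,
not the appearance of real worms:

* **Background** — a constant offset (0.08) plus a smooth tissue field:
  white noise blurred at sigma = min(H, W)/8 and scaled to 0.10. This
  emulates the low-frequency worm-body signal the high-pass filter is
  meant to remove.
* **Spots** — isotropic Gaussian profiles with radius defined as 2 sigma,
  radii uniform in 3–7 px and peak intensities uniform in 0.45–0.85 at the
  512 × 512 default scale. The spot count is Poisson with mean
  `base_spot_count + spot_count_slope · relative_age` (defaults 5 + 20·age).
  Centers are drawn around four fixed aggregation nuclei with Gaussian
  spread `0.25 · min(H, W) · (1 − 0.7 · relative_age)` — clustering
  tightens linearly with age while the nuclei themselves are
  age-independent, mirroring the shared-modes / different-rates premise.
* **Noise** — Poisson shot noise with a photon budget of 400 photons per
  unit intensity at the reference exposure of 1/20 s, scaled
  proportionally with exposure time (1/40 s default, 1/80 s noisiest),
  plus Gaussian read noise of sd 0.01. Ground truth (spot list and stage
  labels) is recorded before noise.
* **Cohorts** — each individual draws a lifespan uniformly from 10–30 days
  (20 °C culture) and contributes one image per day from day 1 to death.
  All randomness derives from a single seed through per-(individual, day)
  seed sequences, so images and manifests are bit-reproducible.

No quantitative count-versus-age law exists for the real reporter; the
linear law and its parameters are synthetic stand-ins chosen to give a
clear but not trivial signal (roughly 5 to 25 expected spots over a
lifespan, against a noise floor that hides the dimmest ones). What passing
tests show is therefore that the pipeline recovers a planted
aggregation–age relationship at realistic SNR; they do not certify
accuracy on real micrographs, where morphology, focus drift, and motion
blur add variation the generator does not emulate.

## Preprocessing

Order: histogram equalization (global, 256 bins) → Gaussian low-pass →
FFT high-pass, then detection; the CNN path instead consumes the
average-pooled raw image. The high-pass is a radial mask with a
raised-cosine edge (zero below cutoff/2, one above 3·cutoff/2), cutoff
0.05 of Nyquist; DC is always removed, so output is zero-mean. The
low-pass sigma defaults to 2.0 px: after global equalization the
background noise band is strongly amplified (equalization is rank-based,
so background ranks spread over most of the output range), and a blur
comparable to the smallest spot scale is needed to pull spot peaks clear
of the noise floor — at sigma 1.5 the smallest spots drown (measured
detection F1 0.86 vs 0.92 at 2.0 on the default conditions).

## Spot detection

The detector combines the classic parameterized threshold-sweep contract
with watershed splitting on local extrema:

1. The conditioned image is clipped at zero and mapped to 8 bits
   robustly: the 99.8th percentile of positive values maps to 128 and
   brighter pixels saturate. Scaling the maximum to 255 instead would let
   one multi-spot pileup compress every other spot toward the noise
   floor.
2. The image is partitioned once into **intensity basins**: markers are
   regional maxima of a sigma-1-smoothed relief (plateaus form one
   connected marker; maxima with a strictly higher point within 4 px, or
   in the border band where the periodic FFT filter leaves artifacts, are
   suppressed), flooded by watershed on the inverted intensity. Touching
   spots therefore separate along their shared valley — the behavior a
   local-extrema watershed detector is meant to have — while each basin
   provides a stable identity for its peak across the whole sweep.
3. Thresholds run 0–255 in steps of 8. At each, the above-threshold part
   of each basin is a candidate region, filtered by area (10–2500 px²),
   circularity ≥ 0.2 (4π·area/perimeter², 2-direction Crofton perimeter
   in the vectorized sweep, 4-direction in the public per-region
   `shape_scores`), convexity ≥ 0.75 (area over Pick's-theorem lattice
   count of the convex hull), and inertia ratio in [0.1, 1]
   (minor/major second-moment axis).
4. A basin whose regions survive at ≥ 6 threshold levels emits one spot:
   mean center, radius of the circle with the mean region area. Finally,
   detections closer than 5 px, or whose circles overlap by more than
   0.75·(r₁+r₂) (duplicate markers on one aggregate), are merged.

The area/shape bounds are the published detector settings; the grouping
radius (5 px), repeatability (6 levels), and marker spacing (4 px) are not
part of that table and were fixed by measuring precision/recall against
generator ground truth at the default conditions: with the loose published
shape bounds, persistence across threshold levels is what separates real
spots (≥ ~8 levels) from equalization-amplified noise bumps (≤ ~5), and a
grouping radius larger than typical in-cluster nearest-neighbor distances
(5–12 px) would re-merge what the watershed split.

**Validation against ground truth.** Two rendered Gaussians whose centers
are closer than the sum of their sigmas produce a single intensity
maximum; counting them as two misses is an identifiability statement, not
a detector error. Detection quality is therefore scored against
*resolvable* ground truth (`synthetic.resolvable_spots`): true spots
within (r₁+r₂)/2 of each other are merged (area-weighted center, larger
radius) before greedy one-to-one matching at a 6 px tolerance. On 50
seeded 256 × 256 images spanning the full age range this gives precision
0.99, recall 0.84, F1 0.91; the residual misses are spots whose
post-equalization peak sits inside the noise band.

## Aggregation features (F2)

For N detected spots, all N(N−1)/2 pairwise center distances are computed,
clipped at the 5000 px sentinel, sorted ascending; the first 12 become
P₁..P₁₂ and missing entries are the sentinel. Clipping before selection
keeps the output non-decreasing even for fields whose diagonal exceeds the
sentinel. Fewer than two spots yield the all-sentinel vector. F2 is
z-scored per dimension on the training set before fusion — raw distances
are O(10²–10³) px and would otherwise dominate the O(1) CNN features.

## Attention backbone (M1)

Compound scaling multiplies base depth, width and resolution by
α^φ, β^φ, γ^φ with the published fitted bases α = 2.3, β = 1.5, γ = 1.18.
Those bases violate the usual FLOPs budget α·β²·γ² ≈ 2 (the product is
≈ 7.21); the scaler accepts them as given and attaches a constraint report
flagging the violation rather than repairing it. Depth rounds up, width
rounds to a multiple of 8, resolution to the nearest integer.

The desk-scale architecture (φ = 0) is a stem 3×3/stride-2 convolution and
four depthwise-separable blocks (depthwise 3×3 + pointwise 1×1, ReLU),
128 px input, 32 final channels, ~4200 parameters. The attention block
passes the final feature map through three 1×1 convolutions
(ReLU, ReLU, sigmoid, each preceded by spatial standardization) to an
attention map A in [0,1] with the feature map's shape; the attention
output is the per-channel ratio **O = GAP(A)/GAP(A⊙F)** with an
epsilon-guarded denominator, applied as a multiplicative gate on the
pooled features. O is identically 1 when F ≡ 1, for any weights — the
identity the implementation asserts to 1e-6.

Weights are drawn once from a seeded truncated normal with He scaling and
kept fixed: the backbone is a deterministic random-projection feature
bank, and supervised fitting is confined to the fusion head. This is the
package's desk-scale design — a full forward-and-backward training of the
convolutional stack is out of scope — and it changes what the M1 path can
show: random convolutional features still carry the global brightness and
texture statistics that track aggregation, but the M1 arm's accuracy is a
floor, not an estimate, of what a trained backbone would reach. No
per-layer normalization is applied inside the frozen stack; with fixed
random weights and no learned statistics, per-image normalization would
discard exactly the global activation magnitude that carries the signal
(measured M1-only accuracy drops from 0.32 to 0.25 with it). Channel
normalization instead happens once, on the pooled F1, with training-set
statistics.

## Fusion head and training

Standardized F1 (32 dims) and F2 (12 dims) are concatenated; the three
experimental arms (M1-only, M2-only, M1+M2) share this code path and
differ only in which block of columns is zero-masked, so ablation
comparisons isolate the paths. The head is Dense(128) + ReLU + inverted
dropout (rate 0.5) + Dense(6) + softmax, trained by mini-batch Adam
(lr 1e-3, batch 32) on categorical cross-entropy with explicit numpy
gradients. Early stopping watches a stratified validation split (15 % of
the training set — 10 % proved too noisy for model selection at
desk-scale cohort sizes) with patience 10 and restores the
best-validation weights. Every source of randomness (shuffling, dropout,
initialization, splits) derives from the config seed, so identical
configs reproduce identical loss histories bit for bit.

## Evaluation

Metrics are one-vs-rest per class: AC = (TP+TN)/total, Recall, Precision,
F1 = 2PR/(P+R) (0 with a log note when P+R = 0). Headline Recall/P/F1 are
macro averages over classes with support; zero-support classes report NaN
and are excluded with a log note. The headline accuracy is trace/total —
reported alongside the mean per-class one-vs-rest AC, which is a distinct
quantity in the multiclass setting. The classical baselines (random
forest, RBF SVM; scikit-learn defaults, fixed seeds) see only the
standardized F2 vectors, never pixels.

## Desk-scale study sizes

Default generator images are 512 × 512; the validation suites run at
256 × 256 with the same absolute spot geometry (the package's bench
scale), cohorts of 20 individuals (≈ 390 images at the 10–30 day lifespan
law), 5 seeds for the directional ablation, and 50 images for detection
scoring. At these sizes the full test suite and the ablation complete on
one CPU in well under half an hour. The directional claims checked are:
fusion accuracy within 0.02 of the best single arm (mean over seeds), M2
clearly above chance when the generator's age signal is on, and M2 at
chance (1/6 ± 0.1) when spot count and clustering are made
age-independent. Absolute accuracies on the original private dataset are
not reproducible and are not asserted.

## Known limitations

* The generator's spot-count law, cluster geometry and noise budget are
  plausible but invented; all downstream accuracy figures are relative to
  this synthetic world.
* The frozen backbone understates the deep path; consequently fusion
  gains over M2 alone are modest at desk scale.
* Spots blended below the two-sigma separation limit are unresolvable by
  construction and excluded from detection scoring rather than solved.
* Single-worm images only; multi-worm fields, anatomy-aware segmentation
  and remaining-lifespan regression are out of scope.
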