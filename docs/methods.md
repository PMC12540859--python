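# Methods

`lbxpheno` models the analysis chain of enrichment-free liquid-biopsy
imaging: every nucleated cell of a blood smear is imaged in four
immunofluorescence (IF) channels — DAPI (nuclear), pan-cytokeratin (CK),
vimentin (VIM) and a multiplexed CD45/CD31 leukocyte/endothelial channel —
segmented, cut into 75×75×5 single-cell crops (4 IF channels + the cell's
binary mask), and embedded either by a contrastively trained CNN (128-dim
representation *h*) or by a 368-dim engineered feature vector. Downstream
benchmarks compare the two feature spaces on linear probing, perturbation
robustness, unsupervised outlier recovery of rare cells, clustering under
class imbalance, and supervised rare-phenotype enumeration.

## Synthetic slide model

Real enrichment-free slides are dominated by white blood cells (WBCs), with
tumor- and vasculature-associated phenotypes at roughly 1:10,000 (0.01%),
the spike-in concentration used for contrived slides. The generator
reproduces that statistical structure:

* **Phenotypes.** Ten classes. Binary marker states follow the IF
  definitions of the ground-truth phenotype table: CTC = DAPI+ CK+;
  imCTC/pcCTC = DAPI+ CK+ CD45/31+; CEC = DAPI+ VIM+ CD45/31+; Mega-like =
  DAPI+ CD45/31+; Fibro-like = DAPI+ VIM+; L-Nuclei = DAPI+ only; Lymph /
  Mono / Gran = DAPI+ CD45/31+. Phenotypes sharing identical binary states
  are separated by intensity tiers and size. These tiers are synthetic
  conventions (the real assay distinguishes them by mass-cytometry markers
  or morphology), so passing benchmarks demonstrate pipeline correctness on
  separable populations, not clinical discriminability.
* **Rendering.** A cell is an anisotropic Gaussian blob pair: a nuclear
  blob in DAPI and a larger concentric cytoplasmic blob in every positive
  channel; negative channels emit low autofluorescence-like signal
  (log-intensity ≈ 6 vs ≈ 8.8–9.8 on the natural-log 16-bit scale, spread
  0.25–0.4). Peak intensities are log-normal; the blob falls to ≈20% of
  peak at the stated cell radius; the truth mask is the elliptical
  footprint at that radius. Rare cells draw larger radii than WBCs
  (cytoplasm ≈ 9.5–12.5 px vs 5.5–7.5 px), reflecting that the spiked cell
  lines and CTCs are selected for their large size; CECs and
  fibroblast-like cells are elongated (axis ratio 1.6–1.7).
* **Sampling.** Class counts are multinomial over the configured fractions
  (marginally Binomial, verified by a χ² goodness-of-fit test), with an
  `exact_counts` option for benchmark cohorts where the spike count is the
  design quantity. Placement is Poisson-disc-style rejection sampling
  (centers at least 0.95× the sum of the two radii apart); cell clusters
  are out of scope.
* **Artifacts.** Additive Gaussian background (level 900, sd 250 counts),
  per-channel gain drawn uniformly in [0.9, 1.1], a smooth regional blur
  field (sharp/blurred blend weighted by a low-frequency random field), and
  per-frame pixel-size drift of ±3% applied to cell radii. Optical PSF
  physics and restaining are not simulated.
* **Determinism.** One integer seed drives a `SeedSequence` tree
  (slide → frame → cell); identical configurations are bit-identical.

What the generator does **not** emulate: staining debris and technical
noise objects, cell clusters and platelet coating, chromatic aberration,
autofocus failures, and the heavy-tailed morphology of real WBCs. Results
on synthetic cohorts therefore validate the machinery and the relative
orderings it measures, not absolute clinical performance.

## Segmentation and evaluation

The segmentation backbone is pluggable (`Segmenter`: frame → instance
mask). The shipped reference segmenter is classical: per-channel smoothing
(σ = 2 px) and median background subtraction, channel summation, peak
detection above 8× the MAD noise floor, watershed assignment, and a
per-basin cut at 12% of the basin's peak (matching the ≈20%-of-peak
footprint convention after smoothing losses). Evaluation is object-level:
one-to-one greedy matching by descending pixel IoU (ties broken by lower
ground-truth id, then lower predicted id), a pair is matchable iff
IoU ≥ threshold, and F1 = 2·TP/(2·TP + FP + FN). Greedy matching equals
maximum bipartite matching on all randomized test scenes; the equivalence
is tested, not assumed. An empty scene (no objects on either side) is
defined as F1 = 1. Crops are centered at the mask centroid (rounded
half-up); windows beyond the frame are zero-padded — padding cannot
fabricate marker signal.

## Engineered features (368)

The engineered space reimplements the classic morphology-profiling
families — size, eccentricity, Haralick texture, intensity statistics on
single channels and channel pairs — in a frozen 368-entry manifest
(`features.feature_names()`, exported as CSV):

* 8 shape features from the mask: area, 4-neighbour boundary-edge
  perimeter, eccentricity, major/minor axis lengths (moment-based), bbox
  extent, circularity, equivalent diameter;
* 10 intensity statistics (mean, median, sd, MAD, min, max, quantiles
  5/25/75/95%) over masked pixels, for 4 channels and the 6 pairwise
  channel-product images (intensities normalized to [0,1] by /65535) → 100;
* 13 classic Haralick statistics per image at pair distances {1, 2} px →
  260. Co-occurrence is computed over masked pixel pairs only, with
  per-crop min–max quantization to 16 gray levels, symmetrized and averaged
  over the four directions after per-direction normalization.

Direction averaging makes every entry invariant to horizontal/vertical
flips (tested at 1e-6 relative). The exact layout of the original
368-dimension EBImage vector is not recoverable from its description;
byte-parity with it is explicitly not a goal — what matters downstream is a
reproducible engineered space of the stated families and size.

## Contrastive encoder

SimCLR-style training on 5-channel crops. Augmentation chain, fixed order,
each stage firing independently with probability p = 0.5: per-channel
brightness/contrast jitter (±0.4), "saturation" as a blend toward the
per-pixel cross-channel mean (±0.4), "hue" as a small random rotation
mixing the three non-DAPI channels (magnitude 0.2 of a full turn) — hue and
saturation are undefined on a 4-channel non-RGB stack, so these are the
package's spectral-perturbation analogues; rotation U[−180°, 180°];
horizontal/vertical flips; translation up to 15 px per axis; Gaussian blur
with a 3-px kernel and σ ~ U[0.5, 3]; random crop to 50–100% of the side,
resized back to 75×75. The mask channel is never jittered or blurred,
moves coherently under geometric stages with nearest-neighbor
interpolation, and stays binary. Consecutive affine stages are composed
into at most two warps (exact for the affine subgroup), evaluated by a
vectorized bilinear/nearest warp with zero fill.

Architecture: four 3×3 convolutions, each followed by batch normalization
and ReLU; after the last convolution a 2×2/stride-2 max-pool and adaptive
average pooling to 1×1; the flattened 128-vector is the representation
*h*; a two-layer head (128→128→64) produces the projection *z* used only
inside the loss. Downstream features always come from *h* — enforced by
the feature-space tag. The NT-Xent loss with cosine similarity and
temperature τ = 0.13 treats every other in-batch sample as a negative and
is averaged over all 2N anchors (averaging, rather than summing, keeps the
loss batch-size comparable); with N = 1 the loss is exactly 0. Optimizer:
Adam with weight decay 1e-4 and a linear warm-up from 1e-3 to 1e-2 over 10
epochs, then flat.

Two profiles: the `paper` profile keeps the published hyperparameters
(widths 32-64-128-128, batch 1024, 50 epochs); the default `desk` profile
uses widths 16-32-64-128, stride-2/3 convolutions, batch 128 and 15
epochs so a full training run takes ~3 minutes on one CPU core. Strides
are unstated in the source architecture and are a CPU-scale choice here.
Input normalization (per-channel mean/sd after /65535) is computed on the
training crops and frozen into the checkpoint.

All three networks (encoder, WBC depletion CNN, enumeration MLPs) run on
an in-package numpy layer library with explicit backpropagation
(channels-last conv via im2col/BLAS, numba-jitted gather/scatter with a
numpy fallback). Analytic gradients are tested against finite differences
at 1e-7; training is bit-deterministic given seed and thread count.

## WBC depletion

A binary CNN (four batch-normalized 3×3 convolutions with ReLU, each
followed by 2×2 max-pooling; global average pooling; dense 128→64→2)
scores p(WBC) for each crop; `deplete` keeps crops with p(WBC) below a
configurable threshold (default 0.5). Trained with Adam at 1e-4 and
cross-entropy, 25 epochs by default (desk tests use 5–8 epochs on small
separable sets), 80:20 stratified validation split. All five crop channels
are fed to the network by default (`use_mask_channel` toggles this; whether
the original classifier saw the mask is unstated).

## Benchmarks

Both feature spaces always run through identical splits, seeds, subsamples
and pixels.

* **Linear probe**: multinomial logistic regression (L2, ≤10,000
  iterations), stratified 80:20 split; accuracy, per-class P/R/F1,
  micro/macro ROC-AUC and PR-AUC, confusion matrix.
* **Robustness**: perturbations are Gaussian blur (σ in px), per-channel
  intensity scaling within ±20%, and isotropic resize within ±10% restored
  to 75×75 by center crop/pad; mask untouched by blur/intensity; drift is
  1 − cosine similarity between original and perturbed features.
* **Outlier detection**: COPOD and ECOD are implemented in-package from
  their published ECDF-tail formulations (score = the largest of the
  left-tail, right-tail and skewness-corrected aggregated −log tail
  probabilities; the two differ in tail-probability convention); iForest is
  scikit-learn's with 100 estimators, seeded. Contamination (default
  0.001) only thresholds flags, never the ranking. Per-feature robust
  scaling (median/IQR) is applied by default to both spaces. Top-K
  recovery walks the K highest scores (K = 0.1% of cells); the reported
  AUC integrates the cumulative hit count over the prefix, normalized by
  the ideal ordering of the hits found there — a perfect ranking scores 1,
  no hit in the prefix scores 0, a random ranking ≈ 0.5.
* **Clustering**: K-means (k = 10, seeded) and Leiden on a symmetrized
  unweighted cosine 15-NN graph with the modularity vertex partition,
  against ground-truth phenotypes via ARI, NMI (arithmetic-mean
  normalization), homogeneity and completeness; the immune:rare ratio is
  swept over [0.5, 10] keeping the rare set fixed. Features are
  L2-normalized before clustering by default, so K-means is spherical
  K-means and both algorithms operate in the same cosine geometry — the
  native geometry of the contrastive representation (its training loss is
  cosine similarity) and the one the Leiden graph is defined in; robust
  scaling and raw coordinates remain available as options.
* **Enumeration**: MLP heads on frozen 128-dim features — two-layer
  (100 epochs, Adam, lr 0.01) and three-layer (50 epochs, lr 0.001, weight
  decay 1e-4) profiles. Reports per-slide and pooled (summed-confusion,
  micro) precision/recall/F1 per rare class; means of per-slide metrics
  are reported separately because the pooled aggregation convention is not
  fixed by convention upstream. Precision with no predicted positives is
  reported as 0 and flagged.

## Desk-scale study sizes

The acceptance tests and `scripts/acceptance.py` run everything at sizes a
single CPU core handles in minutes, chosen once as the package's desk
scale: encoder training on 2,000 balanced crops (200/class, batch 128, 15
epochs; 3 seeds in the tests, 1 in the script); robustness on 300 crops
with blur σ ∈ {0.5, 1, 2} and resize ∈ {0.9, 1.1}; outlier recovery on
WBC-dominated cohorts spiked at 1:10,000 — 20,000 cells × 3 cohorts (2
spiked cells each) in the tests, 50,000 cells × 2 cohorts (5 spiked) in
the script; clustering on a 1,290-cell cohort (90 rare / 1,200 immune —
sized so the 15-NN Leiden graph keeps meaningful neighborhoods at the
smallest ratio, n = 135), ratios {0.5, 2, 5, 10}, metrics averaged over 3
immune-subsample draws per ratio; enumeration trained on two slides whose class profile mirrors
the contrived-model training counts (3,300 other + 680 CTC; 3,300 other +
410 CEC) and evaluated on five held-out slides of 3,050 cells with 30/20
spiked cells — per-slide rare support at desk scale mirrors the annotated
support of full-scale slides rather than raw slide rarity, which would
leave ≤1 rare cell per desk slide and make per-slide F1 undefined noise.

## Numerical choices and degenerate inputs

Empty-scene F1 = 1; undefined precision reported as 0 with a flag;
constant features map to 0 under robust scaling; Haralick correlation of a
constant region is 0; a crop with an empty mask raises (`degenerate
cell`); cosine quantities raise on zero-norm vectors; matching ties break
deterministically; k-means uses 10 restarts with a fixed seed; Leiden uses
the leidenalg seed parameter. Batch statistics in batch norm use the
biased variance; inference uses running statistics, making encoding
batch-size independent to 1e-5.

## Known limitations

Synthetic phenotypes are far more separable than patient data — a random
encoder already probes well above chance on them, so probe comparisons at
desk scale have thin margins by construction. For the same reason the
engineered features, which read the generator's own parameters (marker
intensity, size) off the pixels, are near-optimal on synthetic cohorts:
the learned space wins clustering comparisons under WBC dilution
(immune:rare ratios 2–10) but can be marginally outscored by the
engineered space on rare-dominated subsets (ratio 0.5), where a desk-scale
encoder has no advantage left to offer. The engineered manifest is a
reconstruction of the stated feature families, not a byte-compatible
reimplementation. The reference segmenter is a classical stand-in: it is
adequate for Gaussian-blob synthetic frames and should be replaced by a
learned `Segmenter` for real imagery. Headline numbers from patient and
contrived imaging cohorts require the deposited imaging data and are not
reproduced here; the suite reproduces the comparisons on synthetic cohorts.
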