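# lbxpheno

Deep phenotyping of enrichment-free liquid-biopsy slides. An
enrichment-free whole-slide immunofluorescence (IF) assay images *every*
nucleated cell plated from a blood sample — millions of white blood cells
(WBCs) per slide — so that rare, clinically meaningful populations such as
circulating tumor cells (CTCs, ~1:10,000 cells) are detected by analysis
rather than physical pre-selection. `lbxpheno` implements the full
computational chain for this setting, for computational biologists and
methods developers who want a self-contained, CPU-scale testbed:

* a **synthetic slide generator** that reproduces the statistical structure
  of enrichment-free slides (4 IF channels — DAPI, pan-cytokeratin,
  vimentin, multiplexed CD45/CD31 — phenotype-conditional marker
  expression for 10 cell classes, 1:10,000 spike-ins, size differences,
  scanner artifacts), with per-cell ground truth;
* **instance-segmentation evaluation**: one-to-one object matching by pixel
  IoU and the object-level score `F1 = 2·TP / (2·TP + FP + FN)`, plus a
  pluggable segmenter interface, a classical reference segmenter and
  centered 75×75×5 single-cell crop extraction (4 IF channels + mask);
* a **contrastive (SimCLR-style) encoder**: a stochastic augmentation
  chain, a small batch-normalized CNN producing a 128-dim representation
  *h*, a 64-dim projection *z*, and the NT-Xent loss

  `L(i,j) = −log [ exp(sim(z_i, z_j)/τ) / Σ_{k≠i} exp(sim(z_i, z_k)/τ) ]`

  with cosine similarity, τ = 0.13, averaged over all 2N anchors — every
  other sample in the batch is a negative;
* the **engineered-368 baseline**: a frozen manifest of shape, masked
  intensity statistics (single channels + pairwise channel products) and
  direction-averaged Haralick texture features;
* a **WBC depletion CNN** (binary WBC vs non-WBC) for assembling balanced
  training corpora from WBC-dominated slides;
* the **benchmark suite** comparing learned vs engineered features under
  identical splits and seeds: linear probing, perturbation robustness
  (cosine drift under blur / intensity scaling / resize), rare-cell outlier
  recovery (COPOD, ECOD, iForest; top-K = 0.1% of cells), clustering under
  an immune:rare imbalance sweep (K-means k=10, Leiden on a cosine 15-NN
  graph; ARI/NMI/homogeneity/completeness), and cross-slide rare-phenotype
  enumeration with small MLP heads.

The neural components run on an in-package numpy layer library with
explicit backpropagation, so everything trains in minutes on one CPU core;
see `docs/methods.md` for the model details, desk-scale study sizes and
limitations.

## Worked example

Train a desk-profile encoder on a balanced synthetic crop set and probe
both feature spaces:

```python
from lbxpheno.synthetic import generate_crop_dataset
from lbxpheno.contrastive import train_encoder, EncoderConfig, AugmentationConfig
from lbxpheno.features import engineered_features_batch
from lbxpheno.benchmarks import linear_probe

crops, labels = generate_crop_dataset(50, seed=7)   # 500 crops, 10 phenotypes
model, trace = train_encoder(crops, EncoderConfig(epochs=8),
                             AugmentationConfig(), seed=0)
print(f"contrastive loss: epoch 1 = {trace[0]:.3f} -> epoch 8 = {trace[-1]:.3f}")

h = model.encode(crops)                       # learned-128 representations
res = linear_probe(h.values, labels, split_seed=0)
print(f"linear probe accuracy (learned-128): {res.accuracy:.3f}")

eng = engineered_features_batch(crops)        # engineered-368 baseline
print(f"linear probe accuracy (engineered-368): "
      f"{linear_probe(eng.values, labels, split_seed=0).accuracy:.3f}")
```

Output:

```
contrastive loss: epoch 1 = 5.119 -> epoch 8 = 4.117
linear probe accuracy (learned-128): 0.940
linear probe accuracy (engineered-368): 0.970
```

The contrastive loss falls as the two augmented views of each cell are
pulled together in projection space, and the frozen 128-dim representation
becomes linearly separable by phenotype on held-out cells (0.940 here,
against a 0.10 chance level for 10 balanced classes). On synthetic blobs
the engineered features are also strong — the learned space earns its keep
on *robustness* and *rare-event recovery*, which the benchmark suite
measures (`lbxpheno.benchmarks`, `lbxpheno.outliers`).

A command-line interface mirrors the library
(`lbxpheno simulate | segment | crops | deplete | train-encoder | extract |
benchmark | run`); `lbxpheno run --out RUN --seed 1` executes the whole
pipeline end to end with a provenance manifest.

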