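"""Downstream evaluation suite comparing learned vs engineered features.

Five benchmark families, each run identically on both feature spaces
(shared splits, seeds and subsamples):

* **linear probe** — multinomial logistic regression on frozen features,
  stratified 80:20 split, up to 10,000 iterations;
* **perturbation robustness** — cosine distance between features of original
  and corrupted crops (Gaussian blur, per-channel intensity scaling within
  +/-20%, isotropic resize within +/-10% restored by center crop/pad);
* **outlier detection** — see :mod:`lbxpheno.outliers`;
* **imbalance-swept clustering** — K-means (k=10) and Leiden (cosine 15-NN
  graph, modularity partition) against ground-truth phenotypes while the
  immune:rare ratio is swept over 0.5-10;
* **rare-phenotype enumeration** — small MLP heads (2- or 3-layer) trained
  on a couple of slides and evaluated per held-out slide with
  precision/recall/F1 per rare class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    adjusted_rand_score,
    average_precision_score,
    completeness_score,
    confusion_matrix,
    homogeneity_score,
    normalized_mutual_info_score,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from . import nn
from .outliers import robust_scale
from .types import CROP_SIZE, CellCrop, FeatureMatrix, LbxError, UINT16_MAX

# ---------------------------------------------------------------------------
# linear probe


@dataclass
class ProbeResult:
    accuracy: float
    per_class: pd.DataFrame  # class, precision, recall, f1, support
    roc_auc_macro: float
    roc_auc_micro: float
    pr_auc_macro: float
    pr_auc_micro: float
    confusion: np.ndarray
    classes: np.ndarray


def linear_probe(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence,
    split_seed: int = 0,
    max_iter: int = 10_000,
) -> ProbeResult:
    """Linear separability of phenotypes in a frozen feature space.

    Multinomial logistic regression (L2, up to ``max_iter`` iterations)
    trained on a stratified 80% split and evaluated on the held-out 20%.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise LbxError("linear probe needs at least 2 classes")
    if counts.min() < 2:
        raise LbxError(
            f"class {classes[counts.argmin()]!r} has < 2 members; cannot stratify"
        )
    xtr, xte, ytr, yte = train_test_split(
        x, y, test_size=0.2, stratify=y, random_state=split_seed
    )
    clf = LogisticRegression(max_iter=max_iter)
    clf.fit(xtr, ytr)
    pred = clf.predict(xte)
    proba = clf.predict_proba(xte)
    acc = float((pred == yte).mean())
    cm = confusion_matrix(yte, pred, labels=classes)
    rows = []
    ybin = np.stack([(yte == c).astype(int) for c in classes], axis=1)
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        rows.append(dict(cls=c, precision=p, recall=r, f1=f1, support=int(cm[i].sum())))
    present = ybin.sum(axis=0) > 0
    return ProbeResult(
        accuracy=acc,
        per_class=pd.DataFrame(rows),
        roc_auc_macro=float(roc_auc_score(ybin[:, present], proba[:, present], average="macro")),
        roc_auc_micro=float(roc_auc_score(ybin[:, present], proba[:, present], average="micro")),
        pr_auc_macro=float(average_precision_score(ybin[:, present], proba[:, present], average="macro")),
        pr_auc_micro=float(average_precision_score(ybin[:, present], proba[:, present], average="micro")),
        confusion=cm,
        classes=classes,
    )


# ---------------------------------------------------------------------------
# perturbations


_PERTURB_KINDS = ("gaussian_blur", "intensity_scale", "resize")
_SCALE_RANGE = (0.8, 1.2)
_RESIZE_RANGE = (0.9, 1.1)


@dataclass
class PerturbationSpec:
    """A single controlled image corruption.

    ``magnitude``: blur sigma in px (>= 0), intensity scale factor in
    [0.8, 1.2], or resize factor in [0.9, 1.1].  ``channel`` restricts
    intensity scaling to one IF channel index (None = all four).
    """

    kind: str
    magnitude: float
    channel: int | None = None

    def __post_init__(self):
        if self.kind not in _PERTURB_KINDS:
            raise LbxError(f"unknown perturbation {self.kind!r}")
        if self.kind == "gaussian_blur" and self.magnitude < 0:
            raise LbxError("blur sigma must be >= 0")
        if self.kind == "intensity_scale" and not (
            _SCALE_RANGE[0] <= self.magnitude <= _SCALE_RANGE[1]
        ):
            raise LbxError(f"intensity scale must lie in {_SCALE_RANGE}")
        if self.kind == "resize" and not (
            _RESIZE_RANGE[0] <= self.magnitude <= _RESIZE_RANGE[1]
        ):
            raise LbxError(f"resize factor must lie in {_RESIZE_RANGE}")


def perturb(crop: np.ndarray | CellCrop, spec: PerturbationSpec) -> np.ndarray:
    """Apply exactly one corruption; returns a (5, 75, 75) uint16 stack.

    Blur and intensity scaling never touch the mask channel; resize warps
    all 5 channels (mask nearest-neighbor) and restores 75x75 by center
    crop or zero padding.  Intensities are clipped to the 16-bit range.
    """
    data = crop.data if isinstance(crop, CellCrop) else np.asarray(crop)
    if data.shape != (5, CROP_SIZE, CROP_SIZE):
        raise LbxError(f"crop must be (5, {CROP_SIZE}, {CROP_SIZE})")
    out = data.astype(np.float32)
    if spec.kind == "gaussian_blur":
        if spec.magnitude > 0:
            for c in range(4):
                out[c] = ndimage.gaussian_filter(out[c], spec.magnitude)
    elif spec.kind == "intensity_scale":
        chans = range(4) if spec.channel is None else [spec.channel]
        for c in chans:
            out[c] *= spec.magnitude
    else:  # resize
        f = spec.magnitude
        center = (CROP_SIZE - 1) / 2.0
        A = np.eye(2) / f
        b = np.array([center, center]) - A @ np.array([center, center])
        res = np.empty_like(out)
        for c in range(5):
            if c == 4:
                cval = 0.0
            else:
                # shrinking reveals more field of view, not a dark frame:
                # pad with the channel's median border intensity
                edge = np.concatenate(
                    [out[c, 0, :], out[c, -1, :], out[c, :, 0], out[c, :, -1]]
                )
                cval = float(np.median(edge))
            res[c] = ndimage.affine_transform(
                out[c], A, offset=b, order=(0 if c == 4 else 1),
                mode="constant", cval=cval, prefilter=False,
            )
        out = res
        out[4] = (out[4] >= 0.5).astype(np.float32)
    np.clip(out[:4], 0, UINT16_MAX, out=out[:4])
    res16 = np.rint(out).astype(np.uint16)
    res16[4] = (out[4] >= 0.5).astype(np.uint16)
    return res16


def cosine_drift(f_original: np.ndarray, f_perturbed: np.ndarray) -> np.ndarray:
    """1 - cosine similarity between matching feature rows (in [0, 2])."""
    a = np.atleast_2d(np.asarray(f_original, dtype=float))
    b = np.atleast_2d(np.asarray(f_perturbed, dtype=float))
    if a.shape != b.shape:
        raise LbxError("feature shapes differ")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na <= 0) or np.any(nb <= 0):
        raise LbxError("zero-norm feature vector: cosine undefined")
    sim = np.clip((a * b).sum(axis=1) / (na * nb), -1.0, 1.0)
    return 1.0 - sim


def robustness_report(
    crops: np.ndarray,
    extractors: Mapping[str, callable],
    specs: Sequence[PerturbationSpec],
) -> pd.DataFrame:
    """Mean/sd cosine drift per (feature space, perturbation, magnitude).

    ``extractors`` maps a space name to a callable ``crops -> (n, d) array``;
    at least two extractors are required (the suite exists to compare
    spaces).  Every space sees identical original and perturbed pixels.
    """
    if len(extractors) < 2:
        raise LbxError("robustness comparison needs >= 2 feature extractors")
    crops = np.asarray(crops)
    base = {name: _as_array(fx(crops)) for name, fx in extractors.items()}
    rows = []
    for spec in specs:
        pert = np.stack([perturb(c, spec) for c in crops])
        for name, fx in extractors.items():
            try:
                f2 = _as_array(fx(pert))
            except Exception as e:  # propagate with context
                raise LbxError(f"extractor {name!r} failed on {spec}: {e}") from e
            drift = cosine_drift(base[name], f2)
            rows.append(
                dict(
                    space=name,
                    kind=spec.kind,
                    magnitude=spec.magnitude,
                    channel=spec.channel,
                    mean_drift=float(drift.mean()),
                    sd_drift=float(drift.std()),
                )
            )
    return pd.DataFrame(rows)


def _as_array(f) -> np.ndarray:
    return f.values if isinstance(f, FeatureMatrix) else np.asarray(f)


# ---------------------------------------------------------------------------
# clustering under class imbalance


def subsample_imbalance(
    labels: Sequence,
    is_rare: np.ndarray,
    ratio: float,
    seed: int = 0,
) -> np.ndarray:
    """Indices retaining all rare cells and ``ratio`` x as many immune cells.

    ``ratio`` is the immune/rare count ratio, swept over [0.5, 10] in the
    benchmark.  Immune cells are sampled without replacement; an infeasible
    ratio raises an error stating the maximum feasible value.
    """
    if not (0.5 <= ratio <= 10):
        raise LbxError("ratio must lie in [0.5, 10]")
    is_rare = np.asarray(is_rare).astype(bool)
    rare_idx = np.nonzero(is_rare)[0]
    imm_idx = np.nonzero(~is_rare)[0]
    n_need = int(round(ratio * len(rare_idx)))
    if n_need > len(imm_idx):
        raise LbxError(
            f"not enough immune cells for ratio {ratio}; max feasible "
            f"{len(imm_idx) / max(len(rare_idx), 1):.2f}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(30,)))
    take = rng.choice(imm_idx, size=n_need, replace=False)
    return np.sort(np.concatenate([rare_idx, take]))


def cluster(
    features: FeatureMatrix | np.ndarray,
    method: str = "kmeans",
    seed: int = 0,
    n_clusters: int = 10,
    knn: int = 15,
    scale: str | None = "l2",
) -> np.ndarray:
    """Unsupervised cluster labels: K-means (k=10) or Leiden (cosine 15-NN).

    Leiden builds a cosine-similarity k-NN graph, symmetrizes it (union of
    directed edges, unweighted) and applies the modularity vertex partition;
    both methods are seeded for reproducibility.

    ``scale``: ``"l2"`` (default) row-normalizes features so K-means becomes
    spherical K-means, operating in the same cosine geometry as the Leiden
    graph (the natural geometry of the contrastive representation);
    ``"robust"`` applies per-feature median/IQR scaling; ``None`` uses raw
    coordinates.
    """
    x = _as_array(features).astype(float)
    if scale == "robust":
        x = robust_scale(x)
    elif scale == "l2":
        x = x / np.maximum(np.linalg.norm(x, axis=1, keepdims=True), 1e-12)
    elif scale is not None:
        raise LbxError(f"unknown scaling {scale!r}; use 'l2', 'robust' or None")
    n = len(x)
    if method == "kmeans":
        if n <= n_clusters:
            raise LbxError(f"need more than {n_clusters} points for k-means")
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
        return km.fit_predict(x)
    if method == "leiden":
        import igraph as ig
        import leidenalg

        if n <= knn:
            raise LbxError(f"need more than {knn} points for the k-NN graph")
        nbrs = NearestNeighbors(n_neighbors=knn + 1, metric="cosine").fit(x)
        _, ind = nbrs.kneighbors(x)
        src = np.repeat(np.arange(n), knn)
        dst = ind[:, 1:].ravel()
        edges = {(min(a, b), max(a, b)) for a, b in zip(src, dst) if a != b}
        g = ig.Graph(n=n, edges=sorted(edges), directed=False)
        part = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, seed=seed
        )
        return np.asarray(part.membership)
    raise LbxError(f"unknown clustering method {method!r}")


def clustering_metrics(pred: Sequence, true: Sequence) -> Dict[str, float]:
    """ARI, NMI, homogeneity and completeness of a predicted partition."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if len(pred) != len(true):
        raise LbxError("label vectors differ in length")
    if len(pred) < 2:
        raise LbxError("need at least 2 points")
    return {
        "ari": float(adjusted_rand_score(true, pred)),
        "nmi": float(normalized_mutual_info_score(true, pred)),
        "homogeneity": float(homogeneity_score(true, pred)),
        "completeness": float(completeness_score(true, pred)),
    }


def imbalance_sweep(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence,
    is_rare: np.ndarray,
    ratios: Sequence[float] = (0.5, 2.0, 5.0, 10.0),
    methods: Sequence[str] = ("kmeans", "leiden"),
    seed: int = 0,
) -> pd.DataFrame:
    """Clustering metrics at each immune:rare ratio (same rare set throughout)."""
    x = _as_array(features)
    y = np.asarray(labels)
    rows = []
    for ratio in ratios:
        idx = subsample_imbalance(y, is_rare, ratio, seed=seed)
        for method in methods:
            pred = cluster(x[idx], method=method, seed=seed)
            m = clustering_metrics(pred, y[idx])
            rows.append(dict(method=method, ratio=ratio, n=len(idx), **m))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rare-phenotype enumeration


@dataclass
class EnumeratorModel:
    net: nn.Sequential
    classes: np.ndarray
    head: str

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=np.float32))
        logits = self.net.forward(x, train=False)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.classes[self.predict_proba(features).argmax(axis=1)]


_HEAD_PROFILES = {
    # head spec -> (hidden layer sizes, epochs, lr, weight decay)
    "two-layer": ((64,), 100, 0.01, 0.0),
    "three-layer": ((128, 64), 50, 0.001, 1e-4),
}


def train_enumerator(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence,
    head: str = "two-layer",
    seed: int = 0,
    batch_size: int = 128,
    epochs: int | None = None,
    lr: float | None = None,
    weight_decay: float | None = None,
) -> EnumeratorModel:
    """Train a small MLP head over frozen 128-dim representations.

    ``two-layer`` follows the contrived-slide profile (100 epochs, Adam,
    lr 0.01); ``three-layer`` follows the patient-slide profile (50 epochs,
    lr 0.001, weight decay 1e-4).  Classes are the rare phenotypes plus
    "other"; any string labels are accepted.
    """
    if head not in _HEAD_PROFILES:
        raise LbxError(f"head must be one of {tuple(_HEAD_PROFILES)}")
    hidden, d_epochs, d_lr, d_wd = _HEAD_PROFILES[head]
    epochs = d_epochs if epochs is None else epochs
    lr = d_lr if lr is None else lr
    weight_decay = d_wd if weight_decay is None else weight_decay
    x = _as_array(features).astype(np.float32)
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if len(classes) < 2:
        raise LbxError("enumeration training needs >= 2 classes")
    y = np.searchsorted(classes, y_raw)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(31,)))
    layers: List[nn.Layer] = []
    d_in = x.shape[1]
    for hdim in hidden:
        layers += [nn.Linear(d_in, hdim, rng=rng), nn.ReLU()]
        d_in = hdim
    layers.append(nn.Linear(d_in, len(classes), rng=rng))
    net = nn.Sequential(*layers)
    opt = nn.Adam(net.params(), lr=lr, weight_decay=weight_decay)
    n = len(x)
    for _ in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            out = net.forward(x[idx], train=True)
            _, dlog = nn.softmax_cross_entropy(out, y[idx])
            opt.zero_grad()
            net.backward(dlog)
            opt.step()
    return EnumeratorModel(net=net, classes=classes, head=head)


@dataclass
class EnumerationReport:
    """Per-slide and pooled precision/recall/F1 for each rare class."""

    per_slide: pd.DataFrame  # slide, class, precision, recall, f1, support
    pooled_micro: pd.DataFrame  # class, precision, recall, f1 from summed counts
    per_slide_mean: pd.DataFrame  # class, mean precision/recall/f1 across slides
    undefined_precision: bool = False


def _prf(tp: int, fp: int, fn: int) -> Tuple[float, float, float, bool]:
    flag = tp + fp == 0
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1, flag


def enumerate_slides(
    model: EnumeratorModel,
    slide_features: Mapping[str, np.ndarray],
    slide_truth: Mapping[str, Sequence],
    other_label: str = "other",
) -> EnumerationReport:
    """Evaluate an enumerator per held-out slide and pooled across slides.

    Pooled metrics sum confusion counts over slides (micro); the mean of the
    per-slide metrics is reported separately.  Precision with no predicted
    positives is reported as 0 and flagged.
    """
    if set(slide_features) != set(slide_truth):
        raise LbxError("slide id mismatch between features and truth")
    rare = [c for c in model.classes if c != other_label]
    rows = []
    agg = {c: np.zeros(3, dtype=int) for c in rare}  # tp, fp, fn
    flagged = False
    for slide in sorted(slide_features):
        feats = np.asarray(slide_features[slide])
        truth = np.asarray(slide_truth[slide])
        if len(feats) != len(truth):
            raise LbxError(f"slide {slide!r}: feature/truth length mismatch")
        pred = model.predict(feats)
        for c in rare:
            tp = int(((pred == c) & (truth == c)).sum())
            fp = int(((pred == c) & (truth != c)).sum())
            fn = int(((pred != c) & (truth == c)).sum())
            agg[c] += (tp, fp, fn)
            p, r, f1, flag = _prf(tp, fp, fn)
            flagged |= flag
            rows.append(
                dict(slide=slide, cls=c, precision=p, recall=r, f1=f1,
                     support=int((truth == c).sum()))
            )
    per_slide = pd.DataFrame(rows)
    pooled = []
    for c in rare:
        tp, fp, fn = agg[c]
        p, r, f1, flag = _prf(tp, fp, fn)
        flagged |= flag
        pooled.append(dict(cls=c, precision=p, recall=r, f1=f1, support=int(tp + fn)))
    means = (
        per_slide.groupby("cls")[["precision", "recall", "f1"]].mean().reset_index()
    )
    return EnumerationReport(
        per_slide=per_slide,
        pooled_micro=pd.DataFrame(pooled),
        per_slide_mean=means,
        undefined_precision=flagged,
    )
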