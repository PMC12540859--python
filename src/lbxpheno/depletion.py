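"""Binary WBC vs non-WBC classifier used to deplete common leukocytes.

Enrichment-free slides are dominated by white blood cells; before
representation learning, a small CNN scores every crop and cells confidently
called WBC are removed so the training corpus is not swamped by the majority
class.  Architecture: four batch-normalized 3x3 convolutions with ReLU, each
followed by 2x2 max-pooling, global average pooling, then a two-layer dense
head to 2 logits.  Training: Adam, learning rate 1e-4, cross-entropy, 25
epochs by default, on an 80:20 stratified split.

All 5 crop channels (4 IF + mask) are fed to the network by default; set
``use_mask_channel=False`` to drop the mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import nn
from .types import CROP_SIZE, LbxError, UINT16_MAX

#: class index conventions
NON_WBC, WBC = 0, 1


@dataclass
class DepletionConfig:
    widths: Tuple[int, int, int, int] = (16, 32, 64, 128)
    dense: Tuple[int, int] = (128, 64)
    lr: float = 1e-4
    epochs: int = 25
    batch_size: int = 64
    val_fraction: float = 0.2
    use_mask_channel: bool = True


class DepletionModel:
    """CNN trunk + dense head scoring p(WBC) for 75x75x5 crops."""

    def __init__(self, config: DepletionConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(20,)))
        n_in = 5 if config.use_mask_channel else 4
        in_ch = n_in
        layers: List[nn.Layer] = []
        for w in config.widths:
            layers += [
                nn.Conv2d(in_ch, w, kernel=3, rng=rng),
                nn.BatchNorm2d(w),
                nn.ReLU(),
                nn.MaxPool2d(),
            ]
            in_ch = w
        layers.append(nn.GlobalAvgPool())
        d1, d2 = config.dense
        layers += [
            nn.Linear(config.widths[-1], d2, rng=rng),
            nn.ReLU(),
            nn.Linear(d2, 2, rng=rng),
        ]
        self.net = nn.Sequential(*layers)
        self.norm_mean = np.zeros(n_in, dtype=np.float32)
        self.norm_std = np.ones(n_in, dtype=np.float32)

    def _prepare(self, crops: np.ndarray) -> np.ndarray:
        crops = np.asarray(crops)
        if crops.ndim == 3:
            crops = crops[None]
        if crops.shape[1:] != (5, CROP_SIZE, CROP_SIZE):
            raise LbxError(
                f"expected (n, 5, {CROP_SIZE}, {CROP_SIZE}) crops, got {crops.shape}"
            )
        x = crops.astype(np.float32)
        x[:, :4] /= UINT16_MAX
        if not self.config.use_mask_channel:
            x = x[:, :4]
        x -= self.norm_mean[None, :, None, None]
        x /= self.norm_std[None, :, None, None]
        # layers use channels-last layout
        return np.ascontiguousarray(x.transpose(0, 2, 3, 1))

    def logits(self, crops: np.ndarray, batch_size: int = 512) -> np.ndarray:
        crops = np.asarray(crops)
        if crops.ndim == 3:
            crops = crops[None]
        outs = [
            self.net.forward(self._prepare(crops[lo : lo + batch_size]), train=False)
            for lo in range(0, len(crops), batch_size)
        ]
        return np.concatenate(outs, axis=0)


def wbc_probability(model: DepletionModel, crops: np.ndarray) -> np.ndarray:
    """Softmax probability of the WBC class, one value in [0,1] per crop."""
    lg = model.logits(crops)
    z = lg - lg.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    return p[:, WBC]


def train_depletion(
    crops: np.ndarray,
    labels: Sequence[int],
    config: DepletionConfig | None = None,
    seed: int = 0,
) -> Tuple[DepletionModel, Dict[str, List[float]]]:
    """Train the depletion CNN; returns (model, loss trace).

    ``labels``: 1 for WBC, 0 for non-WBC.  The trace dict holds per-epoch
    ``train_loss`` and ``val_loss`` on the stratified 80:20 split.
    """
    config = config or DepletionConfig()
    crops = np.asarray(crops)
    y = np.asarray(labels, dtype=np.int64)
    classes = np.unique(y)
    if len(classes) < 2:
        raise LbxError("training requires both classes present")
    if not np.isin(classes, (0, 1)).all():
        raise LbxError("labels must be binary (0 = non-WBC, 1 = WBC)")

    ss = np.random.SeedSequence(entropy=seed, spawn_key=(21,))
    rng = np.random.default_rng(ss.spawn(1)[0])
    # stratified split
    val_idx: List[int] = []
    train_idx: List[int] = []
    for c in classes:
        idx = np.nonzero(y == c)[0]
        idx = rng.permutation(idx)
        k = max(1, int(round(config.val_fraction * len(idx))))
        val_idx += list(idx[:k])
        train_idx += list(idx[k:])
    train_idx = np.array(sorted(train_idx))
    val_idx = np.array(sorted(val_idx))

    model = DepletionModel(config, seed=seed)
    x_all = crops.astype(np.float32)
    # frozen normalization constants from the training split
    xt = x_all[train_idx].copy()
    xt[:, :4] /= UINT16_MAX
    if not config.use_mask_channel:
        xt = xt[:, :4]
    model.norm_mean = xt.mean(axis=(0, 2, 3))
    model.norm_std = np.maximum(xt.std(axis=(0, 2, 3)), 1e-4)

    opt = nn.Adam(model.net.params(), lr=config.lr)
    trace: Dict[str, List[float]] = {"train_loss": [], "val_loss": []}
    xv = model._prepare(crops[val_idx])
    yv = y[val_idx]
    for _ in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            if len(idx) < 2:
                continue
            xb = model._prepare(crops[idx])
            out = model.net.forward(xb, train=True)
            loss, dlog = nn.softmax_cross_entropy(out, y[idx])
            opt.zero_grad()
            model.net.backward(dlog)
            opt.step()
            losses.append(loss)
        trace["train_loss"].append(float(np.mean(losses)))
        vout = model.net.forward(xv, train=False)
        vloss, _ = nn.softmax_cross_entropy(vout, yv)
        trace["val_loss"].append(vloss)
    return model, trace


def deplete(
    crops: np.ndarray,
    model: DepletionModel,
    keep_threshold: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Partition crop indices into (kept, removed) by p(WBC) < threshold.

    Returns index arrays into ``crops``; kept + removed is always the full
    input (partition conservation).
    """
    if not (0 < keep_threshold < 1):
        raise LbxError("keep_threshold must lie in (0, 1)")
    p = wbc_probability(model, crops)
    keep = p < keep_threshold
    return np.nonzero(keep)[0], np.nonzero(~keep)[0]
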