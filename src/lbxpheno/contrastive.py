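"""Self-supervised feature encoder for 5-channel single-cell crops.

SimCLR-style training: every crop is augmented twice, both views pass
through a small batch-normalized CNN to a 128-dim representation ``h``, a
two-layer projection head maps ``h`` to a 64-dim ``z``, and the normalized
temperature-scaled cross-entropy (NT-Xent) loss pulls the two views of the
same cell together while every other sample in the batch acts as a negative.
Downstream analyses always consume ``h`` — ``z`` exists only inside the loss.

The stochastic augmentation chain runs in a fixed order, each stage firing
independently with its own probability p:

1. channel jitter (brightness 0.4, contrast 0.4, saturation 0.4, hue 0.2,
   p=0.5) — photometric, IF channels only;
2. rotation uniform in [-180 deg, 180 deg] (p=0.5);
3./4. horizontal / vertical flip (p=0.5 each);
5. translation up to 15 px per axis (p=0.5);
6. Gaussian blur, 3-px kernel, sigma ~ U[0.5, 3] (p=0.5) — IF channels only;
7. random crop to 50-100% of size, resized back to 75x75 (p=0.5).

Hue/saturation are undefined for a 4-channel non-RGB stack; here
"saturation" blends each pixel toward its cross-channel mean and "hue" is a
small random rotation mixing the three non-DAPI channels — spectral
perturbations in the same spirit, well-defined on this assay.  The mask
channel is never jittered or blurred, moves coherently under every geometric
stage (nearest-neighbor) and is re-binarized afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from . import nn
from .types import (
    CROP_SIZE,
    SPACE_LEARNED,
    CellCrop,
    FeatureMatrix,
    LbxError,
    UINT16_MAX,
)

_CENTER = (CROP_SIZE - 1) / 2.0


@dataclass
class AugmentationConfig:
    """Stage probabilities and magnitudes of the augmentation chain."""

    p_jitter: float = 0.5
    brightness: float = 0.4
    contrast: float = 0.4
    saturation: float = 0.4
    hue: float = 0.2
    p_rotate: float = 0.5
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_translate: float = 0.5
    max_translate: float = 15.0
    p_blur: float = 0.5
    blur_sigma: Tuple[float, float] = (0.5, 3.0)
    p_crop: float = 0.5
    crop_scale: Tuple[float, float] = (0.5, 1.0)

    def __post_init__(self):
        for name in ("p_jitter", "p_rotate", "p_hflip", "p_vflip", "p_translate", "p_blur", "p_crop"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise LbxError(f"{name} must lie in [0, 1], got {p}")
        if self.blur_sigma[0] > self.blur_sigma[1] or self.crop_scale[0] > self.crop_scale[1]:
            raise LbxError("malformed augmentation ranges")

    @classmethod
    def none(cls) -> "AugmentationConfig":
        return cls(p_jitter=0, p_rotate=0, p_hflip=0, p_vflip=0, p_translate=0, p_blur=0, p_crop=0)


def _affine_identity():
    return np.eye(2), np.zeros(2)


def _compose(a1, b1, a2, b2):
    # x_in = A1 (A2 x_out + b2) + b1
    return a1 @ a2, a1 @ b2 + b1


def _about_center(A):
    # x_in = A (x_out - c) + c
    c = np.array([_CENTER, _CENTER])
    return A, c - A @ c


_GRID = np.stack(
    np.meshgrid(np.arange(CROP_SIZE), np.arange(CROP_SIZE), indexing="ij")
).reshape(2, -1).astype(np.float32)


def _apply_affine(img: np.ndarray, A, b) -> np.ndarray:
    """Warp a (5, 75, 75) float stack: IF channels bilinear, mask nearest.

    Output coordinates map to input positions ``A @ o + b``; out-of-frame
    samples read 0 (zero padding can never fabricate marker signal).  All
    five channels share one coordinate evaluation, which keeps augmentation
    off the training loop's critical path.
    """
    S = CROP_SIZE
    coords = np.asarray(A, dtype=np.float32) @ _GRID
    coords += np.asarray(b, dtype=np.float32)[:, None]
    r, c = coords[0], coords[1]
    r0 = np.floor(r)
    c0 = np.floor(c)
    fr = r - r0
    fc = c - c0
    i0 = r0.astype(np.int32)
    j0 = c0.astype(np.int32)
    flat = img[:4].reshape(4, -1)
    acc = np.zeros((4, S * S), dtype=img.dtype)
    wr = (np.float32(1.0) - fr, fr)
    wc = (np.float32(1.0) - fc, fc)
    for dr in (0, 1):
        rr = i0 + dr
        ok_r = (rr >= 0) & (rr < S)
        rri = np.clip(rr, 0, S - 1) * S
        for dc in (0, 1):
            cc = j0 + dc
            w = wr[dr] * wc[dc]
            w *= ok_r & (cc >= 0) & (cc < S)
            idx = rri + np.clip(cc, 0, S - 1)
            acc += flat[:, idx] * w
    out = np.empty_like(img)
    out[:4] = acc.reshape(4, S, S)
    rn = np.rint(r).astype(np.int32)
    cn = np.rint(c).astype(np.int32)
    okn = (rn >= 0) & (rn < S) & (cn >= 0) & (cn < S)
    idx = np.clip(rn, 0, S - 1) * S + np.clip(cn, 0, S - 1)
    out[4] = (img[4].ravel()[idx] * okn).reshape(S, S)
    return out


def _jitter(img: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator):
    """Photometric jitter of the 4 IF planes (mask untouched)."""
    x = img[:4]
    b = rng.uniform(1 - cfg.brightness, 1 + cfg.brightness, size=(4, 1, 1))
    x = x * b
    f = rng.uniform(1 - cfg.contrast, 1 + cfg.contrast, size=(4, 1, 1))
    means = x.mean(axis=(1, 2), keepdims=True)
    x = f * x + (1 - f) * means
    s = rng.uniform(1 - cfg.saturation, 1 + cfg.saturation)
    px_mean = x.mean(axis=0, keepdims=True)
    x = s * x + (1 - s) * px_mean
    if cfg.hue > 0:
        theta = 2 * np.pi * rng.uniform(-cfg.hue, cfg.hue)
        axis = np.ones(3) / np.sqrt(3.0)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        x[1:] = np.tensordot(R, x[1:], axes=(1, 0))
    img[:4] = np.clip(x, 0.0, 1.0)
    return img


def augment(
    crop: np.ndarray | CellCrop,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the stochastic augmentation chain to one crop.

    Accepts and returns a ``(5, 75, 75)`` uint16 stack (mask channel binary).
    Consecutive affine stages are composed into a single warp, so each pixel
    is interpolated at most twice (before and after the blur stage).
    """
    data = crop.data if isinstance(crop, CellCrop) else np.asarray(crop)
    if data.shape != (5, CROP_SIZE, CROP_SIZE):
        raise LbxError(f"crop must be (5, {CROP_SIZE}, {CROP_SIZE})")
    img = data.astype(np.float32)
    img[:4] /= UINT16_MAX

    # draw all stage gates first so the stream of random numbers is
    # independent of which stages fire
    gates = rng.random(7)

    if gates[0] < config.p_jitter:
        img = _jitter(img, config, rng)

    A, b = _affine_identity()
    geo = False
    if gates[1] < config.p_rotate:
        th = np.deg2rad(rng.uniform(-180.0, 180.0))
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        A2, b2 = _about_center(R)
        A, b = _compose(A, b, A2, b2)
        geo = True
    if gates[2] < config.p_hflip:
        A2, b2 = _about_center(np.diag([1.0, -1.0]))
        A, b = _compose(A, b, A2, b2)
        geo = True
    if gates[3] < config.p_vflip:
        A2, b2 = _about_center(np.diag([-1.0, 1.0]))
        A, b = _compose(A, b, A2, b2)
        geo = True
    if gates[4] < config.p_translate:
        t = rng.uniform(-config.max_translate, config.max_translate, size=2)
        A, b = _compose(A, b, np.eye(2), -t)
        geo = True

    do_blur = gates[5] < config.p_blur
    sigma = rng.uniform(*config.blur_sigma) if do_blur else 0.0
    do_crop = gates[6] < config.p_crop
    if do_crop:
        s = rng.uniform(*config.crop_scale)
        side = s * CROP_SIZE
        top = rng.uniform(0, CROP_SIZE - side, size=2)
        Ac = np.eye(2) * (side / CROP_SIZE)
        bc = top
    if do_blur:
        if geo:
            img = _apply_affine(img, A, b)
            A, b = _affine_identity()
            geo = False
        # 3-px kernel: truncate the Gaussian at a 1-px radius
        img[:4] = ndimage.gaussian_filter(
            img[:4], (0, sigma, sigma), truncate=1.0 / sigma
        )
    if do_crop:
        A, b = _compose(A, b, Ac, bc)
        geo = True
    if geo:
        img = _apply_affine(img, A, b)

    out = np.empty_like(data, dtype=np.uint16)
    out[:4] = np.rint(np.clip(img[:4], 0, 1) * UINT16_MAX).astype(np.uint16)
    out[4] = img[4].astype(np.uint16)
    return out


def make_view_pair(
    crop: np.ndarray | CellCrop, config: AugmentationConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Two independent augmented views of the same source crop."""
    return augment(crop, config, rng), augment(crop, config, rng)


# ---------------------------------------------------------------------------
# NT-Xent loss


def _normalize_rows(z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms <= 0) or not np.all(np.isfinite(norms)):
        raise LbxError("zero-norm projection vector: cosine similarity undefined")
    return z / norms[:, None], norms


def nt_xent_loss(z_pairs: np.ndarray, temperature: float = 0.13) -> float:
    """Mean NT-Xent loss over all 2N anchors.

    ``z_pairs`` has shape ``(N, 2, D)``: row i holds the two projected views
    of sample i.  For each anchor, the positive is its partner view and every
    other vector in the batch is a negative; similarity is cosine, scaled by
    the temperature.  With N = 1 the loss is exactly 0 (the only non-anchor
    term is the positive itself).
    """
    loss, _ = _nt_xent_with_grad(z_pairs, temperature)
    return loss


def _nt_xent_with_grad(z_pairs: np.ndarray, temperature: float):
    z_pairs = np.asarray(z_pairs, dtype=np.float64)
    if z_pairs.ndim != 3 or z_pairs.shape[1] != 2:
        raise LbxError(f"z_pairs must be (N, 2, D), got {z_pairs.shape}")
    if temperature <= 0:
        raise LbxError("temperature must be positive")
    n2 = 2 * z_pairs.shape[0]
    z = z_pairs.reshape(n2, -1)
    u, norms = _normalize_rows(z)
    S = (u @ u.T) / temperature
    np.fill_diagonal(S, -np.inf)
    pos = np.arange(n2) ^ 1  # partner of 2k is 2k+1 and vice versa
    mx = S.max(axis=1, keepdims=True)
    E = np.exp(S - mx)
    denom = E.sum(axis=1)
    logits_pos = S[np.arange(n2), pos]
    losses = (np.log(denom) + mx[:, 0]) - logits_pos
    loss = float(losses.mean())
    # gradient
    P = E / denom[:, None]
    G = P.copy()
    G[np.arange(n2), pos] -= 1.0
    G /= n2
    du = ((G + G.T) @ u) / temperature
    dz = (du - (du * u).sum(axis=1, keepdims=True) * u) / norms[:, None]
    return loss, dz.reshape(z_pairs.shape)


# ---------------------------------------------------------------------------
# encoder model


@dataclass
class EncoderConfig:
    """Architecture and optimization settings for the contrastive encoder.

    The trunk is four 3x3 convolutions (each + batch norm + ReLU), a final
    2x2/stride-2 max-pool and adaptive average pooling to 1x1; the flattened
    128-dim vector is the representation ``h``.  The projection head maps
    128 -> 128 -> 64.  The ``paper`` profile keeps the published
    hyperparameters (batch 1024, 50 epochs, widths 32-64-128-128); the
    ``desk`` profile shrinks widths/batch/epochs so CPU training finishes in
    minutes.
    """

    widths: Tuple[int, int, int, int] = (16, 32, 64, 128)
    strides: Tuple[int, int, int, int] = (3, 2, 2, 2)
    repr_dim: int = 128
    proj_dim: int = 64
    temperature: float = 0.13
    batch_size: int = 128
    epochs: int = 15
    lr_start: float = 1e-3
    lr_max: float = 1e-2
    warmup_epochs: int = 10
    weight_decay: float = 1e-4

    def __post_init__(self):
        if self.widths[-1] != self.repr_dim:
            raise LbxError("last trunk width must equal the representation dim")
        if self.temperature <= 0:
            raise LbxError("temperature must be positive")
        if self.batch_size < 2:
            raise LbxError("batch size must be >= 2 (loss degenerate otherwise)")

    @classmethod
    def desk(cls, **kw) -> "EncoderConfig":
        return cls(**kw)

    @classmethod
    def paper(cls, **kw) -> "EncoderConfig":
        base = dict(
            widths=(32, 64, 128, 128), batch_size=1024, epochs=50
        )
        base.update(kw)
        return cls(**base)

    def lr_at(self, epoch: int) -> float:
        """Linear warm-up from lr_start to lr_max over warmup_epochs, then flat."""
        if self.warmup_epochs <= 0:
            return self.lr_max
        f = min(epoch / self.warmup_epochs, 1.0)
        return self.lr_start + f * (self.lr_max - self.lr_start)


class ContrastiveEncoder:
    """CNN trunk + projection head with frozen input normalization."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(10,)))
        layers: List[nn.Layer] = []
        in_ch = 5
        for w, s in zip(config.widths, config.strides):
            layers += [
                nn.Conv2d(in_ch, w, kernel=3, stride=s, rng=rng),
                nn.BatchNorm2d(w),
                nn.ReLU(),
            ]
            in_ch = w
        layers += [nn.MaxPool2d(), nn.GlobalAvgPool()]
        self.trunk = nn.Sequential(*layers)
        self.head = nn.Sequential(
            nn.Linear(config.repr_dim, config.repr_dim, rng=rng),
            nn.ReLU(),
            nn.Linear(config.repr_dim, config.proj_dim, rng=rng),
        )
        # frozen per-channel normalization constants (set by fit)
        self.norm_mean = np.zeros(5, dtype=np.float32)
        self.norm_std = np.ones(5, dtype=np.float32)

    # -- input pipeline ----------------------------------------------------
    def set_normalization(self, crops: np.ndarray) -> None:
        x = crops.astype(np.float32)
        x[:, :4] /= UINT16_MAX
        self.norm_mean = x.mean(axis=(0, 2, 3))
        self.norm_std = np.maximum(x.std(axis=(0, 2, 3)), 1e-4)

    def _prepare(self, crops: np.ndarray) -> np.ndarray:
        crops = np.asarray(crops)
        if crops.ndim == 3:
            crops = crops[None]
        if crops.shape[1:] != (5, CROP_SIZE, CROP_SIZE):
            raise LbxError(f"expected (n, 5, {CROP_SIZE}, {CROP_SIZE}) crops, got {crops.shape}")
        x = crops.astype(np.float32)
        x[:, :4] /= UINT16_MAX
        x -= self.norm_mean[None, :, None, None]
        x /= self.norm_std[None, :, None, None]
        # layers use channels-last layout
        return np.ascontiguousarray(x.transpose(0, 2, 3, 1))

    # -- inference ---------------------------------------------------------
    def encode(self, crops: np.ndarray, batch_size: int = 512) -> FeatureMatrix:
        """128-dim representations ``h`` (inference mode, running BN stats).

        Crops are normalized batch by batch so whole-cohort encoding never
        materializes a float copy of the full stack.
        """
        crops = np.asarray(crops)
        if crops.ndim == 3:
            crops = crops[None]
        outs = []
        for lo in range(0, len(crops), batch_size):
            x = self._prepare(crops[lo : lo + batch_size])
            outs.append(self.trunk.forward(x, train=False))
        return FeatureMatrix(np.concatenate(outs, axis=0), space=SPACE_LEARNED)

    def project(self, h: np.ndarray) -> np.ndarray:
        """64-dim projection ``z`` (used only inside the loss)."""
        h = np.atleast_2d(np.asarray(h, dtype=np.float32))
        if h.shape[1] != self.config.repr_dim:
            raise LbxError(f"expected {self.config.repr_dim}-dim h, got {h.shape[1]}")
        return self.head.forward(h, train=False)

    # -- persistence -------------------------------------------------------
    def state_arrays(self):
        arrs = {}
        for i, p in enumerate(self.trunk.params() + self.head.params()):
            arrs[f"p{i:03d}"] = p.value
        bn = [l for l in self.trunk.layers if isinstance(l, nn.BatchNorm2d)]
        for i, l in enumerate(bn):
            arrs[f"bn{i}_mean"] = l.run_mean
            arrs[f"bn{i}_var"] = l.run_var
        arrs["norm_mean"] = self.norm_mean
        arrs["norm_std"] = self.norm_std
        return arrs

    def save(self, path: str) -> None:
        cfg = json.dumps(asdict(self.config))
        np.savez_compressed(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **self.state_arrays())

    @classmethod
    def load(cls, path: str) -> "ContrastiveEncoder":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"].tobytes()).decode())
            model = cls(EncoderConfig(**{**cfg, "widths": tuple(cfg["widths"]),
                                         "strides": tuple(cfg["strides"]),
                                         }), seed=0)
            for i, p in enumerate(model.trunk.params() + model.head.params()):
                p.value = data[f"p{i:03d}"]
            bn = [l for l in model.trunk.layers if isinstance(l, nn.BatchNorm2d)]
            for i, l in enumerate(bn):
                l.run_mean = data[f"bn{i}_mean"]
                l.run_var = data[f"bn{i}_var"]
            model.norm_mean = data["norm_mean"]
            model.norm_std = data["norm_std"]
        return model


def train_encoder(
    crops: np.ndarray,
    config: EncoderConfig | None = None,
    aug: AugmentationConfig | None = None,
    seed: int = 0,
) -> Tuple[ContrastiveEncoder, List[float]]:
    """Train the contrastive encoder; returns (model, per-epoch mean loss).

    Adam with the configured weight decay; learning rate follows the linear
    warm-up schedule.  All randomness (init, shuffling, augmentation) derives
    from ``seed``.
    """
    config = config or EncoderConfig()
    aug = aug or AugmentationConfig()
    crops = np.asarray(crops)
    n = len(crops)
    if n < 2:
        raise LbxError("need at least 2 crops to form negatives")
    model = ContrastiveEncoder(config, seed=seed)
    model.set_normalization(crops)
    opt = nn.Adam(
        model.trunk.params() + model.head.params(),
        lr=config.lr_at(0),
        weight_decay=config.weight_decay,
    )
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(11,))
    shuffle_rng = np.random.default_rng(ss.spawn(1)[0])
    aug_rng = np.random.default_rng(ss.spawn(2)[1])
    trace: List[float] = []
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(epoch)
        order = shuffle_rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            if len(idx) < 2:
                continue
            views = np.empty((2 * len(idx), 5, CROP_SIZE, CROP_SIZE), dtype=np.uint16)
            for k, ci in enumerate(idx):
                views[2 * k], views[2 * k + 1] = make_view_pair(crops[ci], aug, aug_rng)
            x = model._prepare(views)
            h = model.trunk.forward(x, train=True)
            z = model.head.forward(h, train=True)
            loss, dz = _nt_xent_with_grad(
                z.reshape(len(idx), 2, config.proj_dim), config.temperature
            )
            opt.zero_grad()
            dh = model.head.backward(dz.reshape(2 * len(idx), config.proj_dim).astype(np.float32))
            model.trunk.backward(dh)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


def encode(model: ContrastiveEncoder, crops: np.ndarray) -> FeatureMatrix:
    """Module-level alias for :meth:`ContrastiveEncoder.encode`."""
    return model.encode(crops)
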