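"""The 368-dimension engineered baseline feature space.

One vector per 75x75x5 crop, combining the classic families used for cell
morphology profiling:

* 8 shape features computed from the binary center-cell mask (area,
  perimeter, eccentricity, major/minor axis lengths, extent, circularity,
  equivalent diameter);
* 10 intensity statistics (mean, median, sd, MAD, min, max, quantiles
  5/25/75/95%) inside the mask, for each of the 4 IF channels and each of
  the 6 pairwise channel-product images -> 100 features;
* 13 classic Haralick texture statistics per image (10 images), computed on
  masked pixel pairs at distances {1, 2} px, averaged over the four
  directions -> 260 features.

Total: 8 + 100 + 260 = 368.  The layout is frozen; ``feature_names()``
returns the manifest order.  Intensities are normalized to [0, 1] by /65535
before any statistic.  Direction averaging makes every feature invariant
under horizontal/vertical flips.

All heavy paths are vectorized across crops so whole synthetic cohorts
(tens of thousands of cells) can be featurized in seconds on one core.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .types import (
    CHANNELS,
    SPACE_ENGINEERED,
    CellCrop,
    FeatureMatrix,
    LbxError,
)

N_FEATURES = 368
_LEVELS = 16
_DISTANCES = (1, 2)
_SHAPE_NAMES = (
    "area",
    "perimeter",
    "eccentricity",
    "major_axis",
    "minor_axis",
    "extent",
    "circularity",
    "equiv_diameter",
)
_STAT_NAMES = ("mean", "median", "sd", "mad", "min", "max", "q05", "q25", "q75", "q95")
_QUANTS = (0.05, 0.25, 0.75, 0.95)
_HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_avg",
    "sum_var",
    "sum_entropy",
    "entropy",
    "diff_var",
    "diff_entropy",
    "imc1",
    "imc2",
)

_CHAN_SLUG = {"DAPI": "DAPI", "CK": "CK", "VIM": "VIM", "CD45/31": "CD"}
_PAIRS: Tuple[Tuple[int, int], ...] = tuple(
    (i, j) for i in range(4) for j in range(i + 1, 4)
)


def _image_names() -> List[str]:
    singles = [_CHAN_SLUG[c] for c in CHANNELS]
    pairs = [f"{singles[i]}x{singles[j]}" for i, j in _PAIRS]
    return singles + pairs


def feature_names() -> List[str]:
    """The frozen 368-entry manifest, in output order."""
    names = [f"shape_{s}" for s in _SHAPE_NAMES]
    for img in _image_names():
        names += [f"int_{img}_{s}" for s in _STAT_NAMES]
    for img in _image_names():
        for d in _DISTANCES:
            names += [f"har_{img}_d{d}_{h}" for h in _HARALICK_NAMES]
    assert len(names) == N_FEATURES
    return names


# ---------------------------------------------------------------------------
# shape features (vectorized over crops, from raw image moments)


def _shape_features(masks: np.ndarray) -> np.ndarray:
    n = masks.shape[0]
    m = masks.astype(np.float64)
    area = m.sum(axis=(1, 2))
    if (area == 0).any():
        raise LbxError("degenerate cell: empty mask channel")
    rr = np.arange(masks.shape[1], dtype=np.float64)
    cc = np.arange(masks.shape[2], dtype=np.float64)
    sr = (m.sum(axis=2) * rr).sum(axis=1)
    sc = (m.sum(axis=1) * cc).sum(axis=1)
    r0, c0 = sr / area, sc / area
    dr = rr[None, :, None] - r0[:, None, None]
    dc = cc[None, None, :] - c0[:, None, None]
    mu20 = (m * dr * dr).sum(axis=(1, 2)) / area
    mu02 = (m * dc * dc).sum(axis=(1, 2)) / area
    mu11 = (m * dr * dc).sum(axis=(1, 2)) / area
    t = (mu20 + mu02) / 2
    d = np.sqrt(((mu20 - mu02) / 2) ** 2 + mu11**2)
    l1 = t + d
    l2 = np.maximum(t - d, 0.0)
    major = 4.0 * np.sqrt(l1)
    minor = 4.0 * np.sqrt(l2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ecc = np.where(l1 > 0, np.sqrt(np.maximum(1 - l2 / np.maximum(l1, 1e-12), 0)), 0.0)
    # 4-neighbour boundary edge count as the perimeter estimate
    b = masks.astype(np.int8)
    per = (
        np.abs(np.diff(b, axis=1)).sum(axis=(1, 2))
        + np.abs(np.diff(b, axis=2)).sum(axis=(1, 2))
        + b[:, 0, :].sum(axis=1)
        + b[:, -1, :].sum(axis=1)
        + b[:, :, 0].sum(axis=1)
        + b[:, :, -1].sum(axis=1)
    ).astype(np.float64)
    rows_any = masks.any(axis=2)
    cols_any = masks.any(axis=1)
    h_ext = rows_any.sum(axis=1)
    w_ext = cols_any.sum(axis=1)
    # tight bbox extents via first/last occupied row and column
    h_bb = (
        masks.shape[1]
        - np.argmax(rows_any, axis=1)
        - np.argmax(rows_any[:, ::-1], axis=1)
    )
    w_bb = (
        masks.shape[2]
        - np.argmax(cols_any, axis=1)
        - np.argmax(cols_any[:, ::-1], axis=1)
    )
    extent = area / (h_bb * w_bb)
    circ = 4 * np.pi * area / np.maximum(per, 1) ** 2
    eqd = np.sqrt(4 * area / np.pi)
    del h_ext, w_ext
    return np.stack([area, per, ecc, major, minor, extent, circ, eqd], axis=1)


# ---------------------------------------------------------------------------
# masked intensity statistics (segment-sorted, vectorized)


def _segment_quantile(vs: np.ndarray, off: np.ndarray, cnt: np.ndarray, q: float):
    """Linear-interpolated quantile of each sorted segment of ``vs``."""
    pos = off + q * (cnt - 1)
    lo = np.floor(pos).astype(np.int64)
    frac = pos - lo
    hi = np.minimum(lo + 1, off + cnt - 1)
    return vs[lo] * (1 - frac) + vs[hi] * frac


def _masked_stats(img: np.ndarray, ci: np.ndarray, n: int, cnt, off):
    """Ten intensity statistics per crop for one image's masked values.

    ``img`` flattened masked values aligned with crop index ``ci``.
    """
    order = np.lexsort((img, ci))
    vs = img[order]
    sums = np.bincount(ci, weights=img, minlength=n)
    mean = sums / cnt
    sq = np.bincount(ci, weights=img * img, minlength=n)
    sd = np.sqrt(np.maximum(sq / cnt - mean**2, 0.0))
    med = _segment_quantile(vs, off, cnt, 0.5)
    dev = np.abs(img - med[ci])
    dorder = np.lexsort((dev, ci))
    mad = _segment_quantile(dev[dorder], off, cnt, 0.5)
    mn = vs[off]
    mx = vs[off + cnt - 1]
    qs = [_segment_quantile(vs, off, cnt, q) for q in _QUANTS]
    return np.stack([mean, med, sd, mad, mn, mx] + qs, axis=1)


# ---------------------------------------------------------------------------
# Haralick statistics from masked co-occurrence matrices


def _haralick_from_glcm(P: np.ndarray) -> np.ndarray:
    """13 classic Haralick statistics for a batch of normalized GLCMs (n,L,L)."""
    n, L, _ = P.shape
    i = np.arange(L, dtype=np.float64)
    ii = i[None, :, None]
    jj = i[None, None, :]
    eps = 1e-12
    px = P.sum(axis=2)
    py = P.sum(axis=1)
    mux = (px * i).sum(axis=1)
    muy = (py * i).sum(axis=1)
    sx = np.sqrt(np.maximum((px * (i - mux[:, None]) ** 2).sum(axis=1), 0))
    sy = np.sqrt(np.maximum((py * (i - muy[:, None]) ** 2).sum(axis=1), 0))
    asm = (P**2).sum(axis=(1, 2))
    contrast = (P * (ii - jj) ** 2).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = ((P * ii * jj).sum(axis=(1, 2)) - mux * muy) / (sx * sy)
    corr = np.where((sx > eps) & (sy > eps), corr, 0.0)
    var = (P * (ii - mux[:, None, None]) ** 2).sum(axis=(1, 2))
    idm = (P / (1.0 + (ii - jj) ** 2)).sum(axis=(1, 2))
    # sum / difference distributions via one-hot matmuls (fast on BLAS)
    ksum = np.arange(2 * L - 1, dtype=np.float64)
    kdiff = np.arange(L, dtype=np.float64)
    idx_sum = (ii + jj).astype(np.int64)[0].ravel()
    idx_diff = np.abs(ii - jj).astype(np.int64)[0].ravel()
    m_sum = np.zeros((L * L, 2 * L - 1))
    m_sum[np.arange(L * L), idx_sum] = 1.0
    m_dif = np.zeros((L * L, L))
    m_dif[np.arange(L * L), idx_diff] = 1.0
    flat = P.reshape(n, -1)
    pxy = flat @ m_sum
    pdif = flat @ m_dif
    sum_avg = (pxy * ksum).sum(axis=1)
    sum_var = (pxy * (ksum[None, :] - sum_avg[:, None]) ** 2).sum(axis=1)
    sum_ent = -(pxy * np.log(pxy + eps)).sum(axis=1)
    entropy = -(P * np.log(P + eps)).sum(axis=(1, 2))
    dmean = (pdif * kdiff).sum(axis=1)
    diff_var = (pdif * (kdiff[None, :] - dmean[:, None]) ** 2).sum(axis=1)
    diff_ent = -(pdif * np.log(pdif + eps)).sum(axis=1)
    hx = -(px * np.log(px + eps)).sum(axis=1)
    hy = -(py * np.log(py + eps)).sum(axis=1)
    pxpy = px[:, :, None] * py[:, None, :]
    hxy1 = -(P * np.log(pxpy + eps)).sum(axis=(1, 2))
    hxy2 = -(pxpy * np.log(pxpy + eps)).sum(axis=(1, 2))
    denom = np.maximum(np.maximum(hx, hy), eps)
    imc1 = np.where(denom > eps, (entropy - hxy1) / denom, 0.0)
    imc2 = np.sqrt(np.maximum(1 - np.exp(-2.0 * (hxy2 - entropy)), 0.0))
    return np.stack(
        [
            asm,
            contrast,
            corr,
            var,
            idm,
            sum_avg,
            sum_var,
            sum_ent,
            entropy,
            diff_var,
            diff_ent,
            imc1,
            imc2,
        ],
        axis=1,
    )


def _pair_indices(masks: np.ndarray, distance: int):
    """Flat gather indices of masked pixel pairs per direction.

    Returns a list of (crop index, flat index a, flat index b) triples, one
    per direction offset at the given distance.  Pair geometry depends only
    on the mask channel, so these indices are shared by all images.
    """
    n, H, W = masks.shape
    d = distance
    out = []
    for dr, dc in ((0, d), (d, 0), (d, d), (d, -d)):
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        mv = masks[:, r0:r1, c0:c1] & masks[:, r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ci, rr, cc = np.nonzero(mv)
        fa = (rr + r0) * W + (cc + c0)
        fb = (rr + r0 + dr) * W + (cc + c0 + dc)
        out.append((ci, fa, fb))
    return out


def _batch_glcm(qflat: np.ndarray, pairs, n: int) -> np.ndarray:
    """Direction-averaged symmetric masked GLCM for a batch.

    ``qflat`` is the quantized image batch flattened to (n, H*W); ``pairs``
    the per-direction gather indices from :func:`_pair_indices`.  Each
    direction is symmetrized and normalized before averaging (zero-pair
    directions are skipped).
    """
    L = _LEVELS
    acc = np.zeros((n, L * L))
    nd = np.zeros(n)
    for ci, fa, fb in pairs:
        if len(ci) == 0:
            continue
        av = qflat[ci, fa].astype(np.int64)
        bv = qflat[ci, fb].astype(np.int64)
        flat = np.bincount(ci * (L * L) + av * L + bv, minlength=n * L * L).reshape(
            n, L * L
        ) + np.bincount(ci * (L * L) + bv * L + av, minlength=n * L * L).reshape(
            n, L * L
        )
        tot = flat.sum(axis=1)
        has = tot > 0
        acc[has] += flat[has] / tot[has, None]
        nd += has
    out = np.zeros((n, L, L))
    ok = nd > 0
    out[ok] = (acc[ok] / nd[ok, None]).reshape(-1, L, L)
    return out


# ---------------------------------------------------------------------------
# public API


def engineered_features_batch(
    crops: np.ndarray, chunk: int = 2048
) -> FeatureMatrix:
    """Featurize a (n, 5, 75, 75) uint16 crop stack into engineered-368 space."""
    crops = np.asarray(crops)
    if crops.ndim != 4 or crops.shape[1] != 5:
        raise LbxError(f"expected (n, 5, H, W) crops, got {crops.shape}")
    n_all = crops.shape[0]
    out = np.empty((n_all, N_FEATURES))
    for lo in range(0, n_all, chunk):
        hi = min(lo + chunk, n_all)
        out[lo:hi] = _engineered_chunk(crops[lo:hi])
    return FeatureMatrix(out, space=SPACE_ENGINEERED, names=feature_names())


def _engineered_chunk(crops: np.ndarray) -> np.ndarray:
    n = crops.shape[0]
    full_masks = crops[:, 4] > 0
    if not full_masks.any(axis=(1, 2)).all():
        raise LbxError("degenerate cell: empty mask channel")
    feats = [_shape_features(full_masks)]

    # crop every plane to the union bounding box of the masks: texture and
    # intensity statistics only see masked pixels, so this is lossless
    rows_any = np.nonzero(full_masks.any(axis=(0, 2)))[0]
    cols_any = np.nonzero(full_masks.any(axis=(0, 1)))[0]
    rs = slice(rows_any[0], rows_any[-1] + 1)
    cs = slice(cols_any[0], cols_any[-1] + 1)
    masks = full_masks[:, rs, cs]
    norm = crops[:, :4, rs, cs].astype(np.float32) / np.float32(65535.0)
    images = [norm[:, c] for c in range(4)] + [
        norm[:, i] * norm[:, j] for i, j in _PAIRS
    ]

    ci, rr, cc = np.nonzero(masks)
    cnt = np.bincount(ci, minlength=n)
    off = np.concatenate([[0], np.cumsum(cnt)[:-1]])
    stat_blocks = []
    glcm_blocks = []
    pairs = {d: _pair_indices(masks, d) for d in _DISTANCES}
    for img in images:
        vals = img[ci, rr, cc].astype(np.float64)
        stat_blocks.append(_masked_stats(vals, ci, n, cnt, off))
        # per-crop min-max quantization over masked pixels, so co-occurrence
        # statistics describe texture rather than absolute brightness
        vmin = np.full(n, np.inf)
        np.minimum.at(vmin, ci, vals)
        vmax = np.full(n, -np.inf)
        np.maximum.at(vmax, ci, vals)
        scaled = (img - vmin[:, None, None]) / np.maximum(
            (vmax - vmin)[:, None, None], 1e-12
        )
        q = np.clip((scaled * _LEVELS).astype(np.int16), 0, _LEVELS - 1)
        qflat = q.reshape(n, -1)
        for dist in _DISTANCES:
            P = _batch_glcm(qflat, pairs[dist], n)
            glcm_blocks.append(_haralick_from_glcm(P))
    return np.concatenate(feats + stat_blocks + glcm_blocks, axis=1)


def engineered_features(crop: CellCrop | np.ndarray) -> FeatureMatrix:
    """Engineered-368 vector for a single crop (1-row :class:`FeatureMatrix`)."""
    data = crop.data if isinstance(crop, CellCrop) else np.asarray(crop)
    return engineered_features_batch(data[None])
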