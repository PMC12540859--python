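"""Synthetic enrichment-free whole-slide immunofluorescence data.

Emulates the statistical structure of an enrichment-free liquid-biopsy slide:
a supermajority of white blood cells, rare tumor- and vasculature-associated
phenotypes spiked at ~1:10,000 (0.01%), phenotype-conditional marker
expression in the four IF channels (DAPI / CK / VIM / CD45-CD31), size
differences between rare cells and WBCs, additive background noise and
scanner artifacts (regional blur, per-channel gain, pixel-size drift).

Cells are rendered as anisotropic Gaussian blobs — a nuclear blob in DAPI and
a larger concentric cytoplasmic blob in every channel the phenotype expresses
— with log-normal peak intensities mapped into the 16-bit range.  Phenotypes
that share identical binary marker states (e.g. the WBC subclasses, or imCTC
vs pcCTC) are separated by intensity tiers and size; these tiers are synthetic
conventions, not measured biology.

A single integer seed drives a hierarchical seed tree (slide -> frame ->
cell), so identical configurations reproduce bit-identical output.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .types import (
    CHANNELS,
    CROP_CENTER,
    CROP_SIZE,
    PHENOTYPES,
    UINT16_MAX,
    IFFrame,
    InstanceMask,
    LbxError,
    MarkerProfile,
    SlideConfig,
    SlideTruth,
)

import pandas as pd

# Log-intensity tiers (natural log of 16-bit counts).  "negative" channels
# still emit low autofluorescence-like signal.
_NEG = (6.0, 0.40)  # ~400 counts
_HI = 9.8  # ~18,000 counts
_MID = 9.3
_LO = 8.8
_SD = 0.25

# phenotype -> (CK state, VIM state, CD45/31 state,
#               DAPI mu, CK mu, VIM mu, CD mu,
#               nucleus radius (mu, sd), cytoplasm radius (mu, sd), elongation)
_PROFILE_TABLE: Dict[str, tuple] = {
    # rare classes: large cells
    "CTC":        (True,  False, False, 9.7, _HI,  None, None, (6.5, 0.7), (11.0, 1.1), 1.15),
    "imCTC":      (True,  False, True,  9.6, 9.4,  None, _MID, (6.5, 0.7), (10.5, 1.1), 1.15),
    "pcCTC":      (True,  False, True,  9.6, _HI,  None, 9.6,  (7.0, 0.7), (11.5, 1.1), 1.25),
    "CEC":        (False, True,  True,  9.5, None, 9.5,  _MID, (6.0, 0.6), (10.0, 1.0), 1.60),
    "Mega-like":  (False, False, True,  _HI, None, None, _MID, (9.0, 0.9), (12.5, 1.2), 1.20),
    "Fibro-like": (False, True,  False, 9.5, None, 9.7,  None, (6.0, 0.6), (11.0, 1.1), 1.70),
    "L-Nuclei":   (False, False, False, _HI, None, None, None, (8.5, 0.8), (9.5, 0.9),  1.20),
    # common WBC subclasses: small cells, CD45/31 intensity tiers
    "Lymph":      (False, False, True,  9.5, None, None, _HI,  (4.5, 0.5), (5.5, 0.5),  1.10),
    "Mono":       (False, False, True,  9.4, None, None, _MID, (6.0, 0.6), (7.5, 0.7),  1.15),
    "Gran":       (False, False, True,  9.3, None, None, _LO,  (5.5, 0.5), (6.5, 0.6),  1.10),
}


def marker_profile(phenotype: str) -> MarkerProfile:
    """Default rendering profile for one of the ten phenotypes.

    Expression states follow the IF marker definitions of the ground-truth
    phenotype table (DAPI is positive for every class; e.g. CTC is DAPI+ CK+
    only, CEC is DAPI+ VIM+ CD45/31+, L-Nuclei is DAPI+ only).
    """
    if phenotype not in _PROFILE_TABLE:
        raise LbxError(f"unknown phenotype {phenotype!r}")
    ck, vim, cd, dapi_mu, ck_mu, vim_mu, cd_mu, nuc, cyto, _ = _PROFILE_TABLE[phenotype]
    expr = {"DAPI": True, "CK": ck, "VIM": vim, "CD45/31": cd}
    mus = {"DAPI": dapi_mu, "CK": ck_mu, "VIM": vim_mu, "CD45/31": cd_mu}
    logint = {
        ch: ((mus[ch], _SD) if expr[ch] else _NEG) for ch in CHANNELS
    }
    return MarkerProfile(
        phenotype=phenotype,
        expression=expr,
        log_intensity=logint,
        nucleus_radius=nuc,
        cytoplasm_radius=cyto,
    )


def _elongation(phenotype: str) -> float:
    return _PROFILE_TABLE[phenotype][-1]


def class_probabilities(config: SlideConfig) -> Dict[str, float]:
    """Expected per-phenotype fractions implied by a slide config."""
    probs = {p: 0.0 for p in PHENOTYPES}
    probs.update({p: float(f) for p, f in config.rarity.items()})
    rest = 1.0 - sum(probs.values())
    wbc_total = sum(config.wbc_mix.values())
    for p, w in config.wbc_mix.items():
        probs[p] += rest * w / wbc_total
    return probs


def sample_phenotypes(config: SlideConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw per-cell phenotype labels (multinomial; marginals are Binomial)."""
    if config.exact_counts is not None:
        labels = []
        for p, c in config.exact_counts.items():
            if p not in PHENOTYPES:
                raise LbxError(f"unknown phenotype {p!r}")
            labels += [p] * int(c)
        n_rest = config.n_cells - len(labels)
        if n_rest < 0:
            raise LbxError("exact counts exceed total cell count")
        wbc = list(config.wbc_mix)
        w = np.array([config.wbc_mix[p] for p in wbc], dtype=float)
        fill = rng.choice(wbc, size=n_rest, p=w / w.sum())
        labels = np.array(labels + list(fill))
        rng.shuffle(labels)
        return labels
    probs = class_probabilities(config)
    names = list(probs)
    counts = rng.multinomial(config.n_cells, np.array([probs[p] for p in names]))
    labels = np.repeat(names, counts)
    rng.shuffle(labels)
    return labels


def _draw_cell_params(labels: Sequence[str], rng: np.random.Generator):
    """Per-cell geometry and per-channel peak intensities (vectorized)."""
    labels = np.asarray(labels)
    n = len(labels)
    nuc = np.empty(n)
    cyto = np.empty(n)
    elong = np.empty(n)
    theta = rng.uniform(0, np.pi, size=n)
    amps = np.empty((n, 4))
    # grouped by phenotype so parameter draws vectorize; draw order is fixed
    # by the sorted class list, keeping the stream reproducible
    for lab in sorted(set(labels.tolist())):
        sel = np.nonzero(labels == lab)[0]
        prof = marker_profile(lab)
        m = len(sel)
        nuc[sel] = np.maximum(
            rng.normal(prof.nucleus_radius[0], prof.nucleus_radius[1], size=m), 2.0
        )
        cyto[sel] = np.maximum(
            rng.normal(prof.cytoplasm_radius[0], prof.cytoplasm_radius[1], size=m),
            nuc[sel] + 0.5,
        )
        elong[sel] = _elongation(lab)
        for c, ch in enumerate(CHANNELS):
            mu, sd = prof.log_intensity[ch]
            amps[sel, c] = np.exp(rng.normal(mu, sd, size=m))
    np.clip(amps, 0, UINT16_MAX, out=amps)
    return nuc, cyto, elong, theta, amps


def _blob_profiles(rr, cc, r0, c0, nuc, cyto, elong, theta):
    """Nucleus / cytoplasm Gaussian profiles and elliptical footprint.

    ``rr, cc`` are broadcastable coordinate grids; remaining args are scalars
    or (n,1,1) arrays.  Returns (nucleus, cytoplasm, footprint) arrays.
    """
    dr = rr - r0
    dc = cc - c0
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    # Gaussian sigma chosen so the blob falls to ~20% at the stated radius;
    # the nucleus shares the cytoplasm's quadratic form up to a radius ratio
    q = (u / cyto) ** 2 + (v * (elong / cyto)) ** 2
    k = np.float32(1.8) ** 2
    cb = np.exp(np.float32(-0.5) * k * q)
    ratio2 = ((cyto / nuc) ** 2).astype(q.dtype) if hasattr(cyto, "astype") else (cyto / nuc) ** 2
    nb = np.exp(np.float32(-0.5) * k * q * ratio2)
    foot = q <= 1.0
    return nb, cb, foot


def render_crops(
    labels: Sequence[str],
    seed: int | np.random.Generator,
    background_level: float = 900.0,
    background_noise: float = 250.0,
    jitter_px: float = 1.5,
    chunk: int = 2048,
) -> np.ndarray:
    """Render one centered cell per label into a (n, 5, 75, 75) uint16 stack.

    The cell center is jittered by up to ``jitter_px`` around the crop center
    pixel (37, 37) to emulate centroid-rounding variation; channel 5 is the
    cell's elliptical footprint mask.
    """
    labels = np.asarray(labels)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(seed))
    )
    n = len(labels)
    out = np.empty((n, 5, CROP_SIZE, CROP_SIZE), dtype=np.uint16)
    rr = np.arange(CROP_SIZE, dtype=np.float32)[None, :, None]
    cc = np.arange(CROP_SIZE, dtype=np.float32)[None, None, :]
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        labs = labels[lo:hi]
        m = hi - lo
        nuc, cyto, elong, theta, amps = _draw_cell_params(labs, rng)
        jit = rng.uniform(-jitter_px, jitter_px, size=(m, 2))
        r0 = (CROP_CENTER + jit[:, 0]).astype(np.float32)[:, None, None]
        c0 = (CROP_CENTER + jit[:, 1]).astype(np.float32)[:, None, None]
        sh = lambda a: a.astype(np.float32)[:, None, None]  # noqa: E731
        nb, cb, foot = _blob_profiles(
            rr, cc, r0, c0, sh(nuc), sh(cyto), sh(elong), sh(theta)
        )
        planes = rng.standard_normal(size=(m, 4, CROP_SIZE, CROP_SIZE), dtype=np.float32)
        planes *= np.float32(background_noise)
        planes += np.float32(background_level)
        amps32 = amps.astype(np.float32)
        planes[:, 0] += amps32[:, 0, None, None] * nb
        planes[:, 1:] += amps32[:, 1:, None, None] * cb[:, None, :, :]
        np.clip(planes, 0, UINT16_MAX, out=planes)
        np.rint(planes, out=planes)
        out[lo:hi, :4] = planes
        out[lo:hi, 4] = foot
    return out


def generate_crop_dataset(
    n_per_class: int,
    phenotypes: Sequence[str] | None = None,
    seed: int = 0,
    **render_kw,
) -> Tuple[np.ndarray, np.ndarray]:
    """Balanced labeled crop set: (crops (n,5,75,75) uint16, labels (n,) str)."""
    if phenotypes is None:
        phenotypes = PHENOTYPES
    phenotypes = tuple(phenotypes)
    if not phenotypes:
        raise LbxError("phenotype set must be non-empty")
    if n_per_class < 1:
        raise LbxError("n_per_class must be >= 1")
    for p in phenotypes:
        if p not in PHENOTYPES:
            raise LbxError(f"unknown phenotype {p!r}")
    labels = np.repeat(phenotypes, n_per_class)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    rng = np.random.default_rng(ss)
    perm = rng.permutation(len(labels))
    labels = labels[perm]
    crops = render_crops(labels, rng, **render_kw)
    return crops, labels


def _place_cells(
    radii: np.ndarray,
    shape: Tuple[int, int],
    margin: int,
    rng: np.random.Generator,
    allow_clusters: bool,
    max_tries: int = 40,
) -> np.ndarray:
    """Poisson-disc-style rejection sampling of cell centers.

    Rejects candidates closer than the sum of the two cells' radii (scaled by
    0.95) unless ``allow_clusters``.  Returns (n, 2) float centers.
    """
    h, w = shape
    n = len(radii)
    if n == 0:
        return np.empty((0, 2))
    cell = max(2.0 * float(radii.max()), 8.0)
    gh, gw = int(h / cell) + 1, int(w / cell) + 1
    grid: Dict[Tuple[int, int], list] = {}
    centers = np.empty((n, 2))
    for i in range(n):
        ri = radii[i]
        placed = False
        for _ in range(max_tries):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if allow_clusters:
                placed = True
                break
            gr, gc = int(r / cell), int(c / cell)
            ok = True
            for dgr in (-1, 0, 1):
                for dgc in (-1, 0, 1):
                    for j in grid.get((gr + dgr, gc + dgc), ()):
                        dr = centers[j, 0] - r
                        dc = centers[j, 1] - c
                        if dr * dr + dc * dc < (0.95 * (ri + radii[j])) ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                placed = True
                break
        if not placed:
            raise LbxError(
                f"could not place cell {i} of {n}: requested density infeasible "
                f"for frame area {h}x{w}"
            )
        centers[i] = (r, c)
        grid.setdefault((int(r / cell), int(c / cell)), []).append(i)
    return centers


def generate_slide(
    config: SlideConfig,
) -> Tuple[list, list, SlideTruth]:
    """Generate a synthetic slide: frames, instance masks and ground truth.

    Returns ``(frames, masks, truth)`` where ``frames`` is a list of
    :class:`IFFrame`, ``masks`` the aligned :class:`InstanceMask` list and
    ``truth`` the per-cell table (ids unique across the slide, 1-based and
    frame-local label values equal to the cell id).
    """
    h, w = config.frame_shape
    root = np.random.SeedSequence(entropy=config.seed, spawn_key=(0,))
    slide_rng = np.random.default_rng(root.spawn(1)[0])
    labels = sample_phenotypes(config, slide_rng)
    n = len(labels)

    # rough feasibility check before attempting placement
    mean_r = float(np.mean([marker_profile(p).cytoplasm_radius[0] for p in PHENOTYPES]))
    if n * (2 * mean_r) ** 2 > 0.6 * config.n_frames * h * w:
        raise LbxError(
            f"requested {n} cells infeasible for {config.n_frames} frame(s) of {h}x{w}"
        )

    frame_of = slide_rng.integers(0, config.n_frames, size=n)
    frames: list = []
    masks: list = []
    rows = []
    frame_seeds = root.spawn(config.n_frames)
    next_id = 1
    for fi in range(config.n_frames):
        frng = np.random.default_rng(frame_seeds[fi])
        idx = np.nonzero(frame_of == fi)[0]
        labs = labels[idx]
        nuc, cyto, elong, theta, amps = _draw_cell_params(labs, frng)
        pixel_size = 1.0
        if config.artifacts and config.pixel_size_jitter > 0:
            pixel_size = 1.0 + frng.uniform(
                -config.pixel_size_jitter, config.pixel_size_jitter
            )
            nuc, cyto = nuc * pixel_size, cyto * pixel_size
        centers = _place_cells(
            cyto, (h, w), config.min_margin, frng, config.allow_clusters
        )
        planes = config.background_level + config.background_noise * frng.standard_normal(
            size=(4, h, w), dtype=np.float32
        )
        label_plane = np.zeros((h, w), dtype=np.int32)
        for k in range(len(idx)):
            r0, c0 = centers[k]
            rad = int(np.ceil(2.2 * cyto[k]))
            r_lo, r_hi = max(0, int(r0) - rad), min(h, int(r0) + rad + 1)
            c_lo, c_hi = max(0, int(c0) - rad), min(w, int(c0) + rad + 1)
            rr = np.arange(r_lo, r_hi, dtype=np.float32)[:, None]
            cc = np.arange(c_lo, c_hi, dtype=np.float32)[None, :]
            nb, cb, foot = _blob_profiles(
                rr, cc, r0, c0, nuc[k], cyto[k], elong[k], theta[k]
            )
            planes[0, r_lo:r_hi, c_lo:c_hi] += np.float32(amps[k, 0]) * nb
            for c in range(1, 4):
                planes[c, r_lo:r_hi, c_lo:c_hi] += np.float32(amps[k, c]) * cb
            patch = label_plane[r_lo:r_hi, c_lo:c_hi]
            patch[foot & (patch == 0)] = next_id
            area = int(foot.sum())
            rows.append(
                dict(
                    cell_id=next_id,
                    frame=fi,
                    row=float(r0),
                    col=float(c0),
                    phenotype=labs[k],
                    area=area,
                )
            )
            next_id += 1
        if config.artifacts:
            gains = frng.uniform(*config.gain_range, size=4).astype(np.float32)
            planes *= gains[:, None, None]
            lo_s, hi_s = config.blur_sigma_range
            if hi_s > 0:
                # smooth regional blur: blend sharp and blurred copies with a
                # low-frequency weight field
                field = frng.standard_normal(size=(8, 11)).astype(np.float32)
                field = ndimage.zoom(field, (h / 8, w / 11), order=1)
                field = (field - field.min()) / max(float(np.ptp(field)), 1e-6)
                wgt = field * ((hi_s - lo_s) / max(hi_s, 1e-6))
                blurred = np.stack(
                    [ndimage.gaussian_filter(p, hi_s) for p in planes]
                )
                planes = planes * (1 - wgt) + blurred * wgt
        np.clip(planes, 0, UINT16_MAX, out=planes)
        frames.append(IFFrame(np.rint(planes).astype(np.uint16), pixel_size=pixel_size))
        masks.append(InstanceMask(label_plane))
    truth = SlideTruth(
        pd.DataFrame(rows, columns=["cell_id", "frame", "row", "col", "phenotype", "area"])
    )
    return frames, masks, truth
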