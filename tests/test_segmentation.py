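"""Object matching, F1@IoU and crop extraction against brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from lbxpheno.segmentation import (
    MatchResult,
    extract_crop,
    f1_at_iou,
    f1_curve,
    match_instances,
    reference_segment,
)
from lbxpheno.synthetic import generate_slide
from lbxpheno.types import IFFrame, InstanceMask, LbxError, SlideConfig


def _random_scene(rng, shape=(48, 48), max_objects=12):
    """A labeled mask of random rectangles (later labels overwrite earlier)."""
    lab = np.zeros(shape, dtype=np.int32)
    n = rng.integers(1, max_objects + 1)
    for i in range(1, n + 1):
        h = rng.integers(3, 12)
        w = rng.integers(3, 12)
        r = rng.integers(0, shape[0] - h)
        c = rng.integers(0, shape[1] - w)
        lab[r : r + h, c : c + w] = i
    return InstanceMask(lab)


def _oracle_match(gt: InstanceMask, pred: InstanceMask, thr: float):
    """Exhaustive all-pairs IoU + maximum bipartite matching (oracle)."""
    g_ids = gt.ids
    p_ids = pred.ids
    iou = np.zeros((len(g_ids), len(p_ids)))
    for i, g in enumerate(g_ids):
        gm = gt.labels == g
        for j, p in enumerate(p_ids):
            pm = pred.labels == p
            inter = np.logical_and(gm, pm).sum()
            union = np.logical_or(gm, pm).sum()
            iou[i, j] = inter / union if union else 0.0
    # maximize number of matches among pairs meeting the threshold
    score = (iou >= thr).astype(float)
    if score.size == 0:
        tp = 0
    else:
        ri, ci = linear_sum_assignment(-score)
        tp = int(score[ri, ci].sum())
    return tp, len(p_ids) - tp, len(g_ids) - tp


def test_match_identical_masks():
    rng = np.random.default_rng(0)
    m = _random_scene(rng)
    res = match_instances(m, m, 0.5)
    assert (res.tp, res.fp, res.fn) == (len(m.ids), 0, 0)
    assert f1_at_iou(res) == 1.0


def test_match_empty_prediction():
    gt = np.zeros((20, 20), dtype=np.int32)
    gt[1:4, 1:4] = 1
    gt[6:9, 6:9] = 2
    gt[11:14, 1:4] = 3
    gt[15:19, 15:19] = 4
    res = match_instances(InstanceMask(gt), InstanceMask(np.zeros_like(gt)), 0.5)
    assert (res.tp, res.fp, res.fn) == (0, 0, 4)
    assert f1_at_iou(res) == 0.0


def test_shifted_square_iou_third():
    """10x10 square shifted by 5 columns: IoU = 50/150 = 1/3 exactly."""
    gt = np.zeros((20, 20), dtype=np.int32)
    gt[5:15, 2:12] = 1
    pr = np.zeros_like(gt)
    pr[5:15, 7:17] = 1
    lo = match_instances(InstanceMask(gt), InstanceMask(pr), 0.3)
    hi = match_instances(InstanceMask(gt), InstanceMask(pr), 0.5)
    assert lo.tp == 1 and lo.pairs[0][2] == pytest.approx(1 / 3)
    assert (hi.tp, hi.fp, hi.fn) == (0, 1, 1)
    assert f1_curve(InstanceMask(gt), InstanceMask(pr), (0.3, 0.5)) == [
        (0.3, 1.0),
        (0.5, 0.0),
    ]


@pytest.mark.parametrize("thr", [0.3, 0.5, 0.75])
def test_matching_agrees_with_exhaustive_oracle(thr):
    rng = np.random.default_rng(99)
    for _ in range(100):
        gt = _random_scene(rng)
        pred = _random_scene(rng)
        res = match_instances(gt, pred, thr)
        tp, fp, fn = _oracle_match(gt, pred, thr)
        assert (res.tp, res.fp, res.fn) == (tp, fp, fn)
        # matched pairs respect the threshold and one-to-one constraint
        gs = [a for a, _, _ in res.pairs]
        ps = [b for _, b, _ in res.pairs]
        assert len(set(gs)) == len(gs) and len(set(ps)) == len(ps)
        assert all(v >= thr for _, _, v in res.pairs)


def test_f1_values():
    assert f1_at_iou(MatchResult(0.5, 5, 0, 0, [(i, i, 1.0) for i in range(5)])) == 1.0
    assert f1_at_iou(MatchResult(0.5, 0, 2, 3)) == 0.0
    assert f1_at_iou(MatchResult(0.5, 3, 1, 2, [(1, 1, 0.9), (2, 2, 0.8), (3, 3, 0.7)])) == pytest.approx(6 / 9)
    # empty scene convention
    assert f1_at_iou(MatchResult(0.5, 0, 0, 0)) == 1.0


def test_f1_curve_non_increasing():
    rng = np.random.default_rng(5)
    th = np.linspace(0.1, 0.9, 9)
    for _ in range(20):
        gt = _random_scene(rng)
        pred = _random_scene(rng)
        curve = [v for _, v in f1_curve(gt, pred, th)]
        assert all(a >= b - 1e-12 for a, b in zip(curve, curve[1:]))


def test_match_shape_mismatch_errors():
    a = InstanceMask(np.zeros((5, 5), dtype=np.int32))
    b = InstanceMask(np.zeros((6, 5), dtype=np.int32))
    with pytest.raises(LbxError):
        match_instances(a, b, 0.5)
    with pytest.raises(LbxError):
        match_instances(a, a, 1.5)


# ---------------------------------------------------------------------------
# reference segmenter


def test_reference_segmenter_on_sparse_nuclei():
    """Well-separated synthetic nuclei are each recovered (F1@0.5 = 1)."""
    cfg = SlideConfig(
        n_cells=5, frame_shape=(300, 400), rarity={}, seed=21, artifacts=False
    )
    frames, masks, _ = generate_slide(cfg)
    pred = reference_segment(frames[0])
    assert len(pred.ids) == 5
    assert f1_at_iou(match_instances(masks[0], pred, 0.5)) == 1.0


def test_reference_segmenter_blank_frame():
    frame = IFFrame(np.zeros((4, 64, 64), dtype=np.uint16))
    assert len(reference_segment(frame).ids) == 0


def test_reference_segmenter_deterministic():
    cfg = SlideConfig(n_cells=40, frame_shape=(300, 400), seed=22)
    frames, _, _ = generate_slide(cfg)
    a = reference_segment(frames[0])
    b = reference_segment(frames[0])
    assert np.array_equal(a.labels, b.labels)


# ---------------------------------------------------------------------------
# crop extraction


def _toy_frame_with_cells():
    rng = np.random.default_rng(3)
    img = (rng.random((4, 120, 140)) * 1000).astype(np.uint16)
    lab = np.zeros((120, 140), dtype=np.int32)
    lab[50:60, 60:72] = 1  # interior cell, area 120
    lab[50:60, 72:80] = 2  # adjacent cell
    lab[5:15, 5:15] = 3  # near-border cell centered ~(10, 10)
    return IFFrame(img), InstanceMask(lab)


def test_extract_crop_interior_area_bookkeeping():
    frame, mask = _toy_frame_with_cells()
    crop = extract_crop(frame, mask, 1)
    assert crop.data.shape == (5, 75, 75)
    assert crop.data[4].sum() == 120
    # center pixel inside the cell
    assert crop.data[4, 37, 37] == 1


def test_extract_crop_zero_pads_border_cells():
    frame, mask = _toy_frame_with_cells()
    crop = extract_crop(frame, mask, 3)
    assert crop.data.shape == (5, 75, 75)
    # cell 3 centroid is (10, 10): the first 27 rows/cols fall outside the
    # frame and must be zero-padded, the rest carries frame content
    assert crop.data[:, :27, :].sum() == 0
    assert crop.data[:, :, :27].sum() == 0
    assert crop.data[:4, 27:, 27:].sum() > 0
    assert crop.data[4].sum() == 100


def test_extract_crop_excludes_neighbor_masks():
    frame, mask = _toy_frame_with_cells()
    crop = extract_crop(frame, mask, 1)
    # cell 2 occupies columns just right of cell 1; its mask must be zeroed
    assert crop.data[4].sum() == (mask.labels == 1).sum()


def test_extract_crop_missing_id_errors():
    frame, mask = _toy_frame_with_cells()
    with pytest.raises(LbxError, match="99"):
        extract_crop(frame, mask, 99)


def test_extract_crop_translation_consistent():
    """Shifting frame and mask together leaves interior crops unchanged."""
    frame, mask = _toy_frame_with_cells()
    dr, dc = 7, 11
    ch = np.roll(np.roll(frame.channels, dr, axis=1), dc, axis=2)
    lb = np.roll(np.roll(mask.labels, dr, axis=0), dc, axis=1)
    c0 = extract_crop(frame, mask, 1)
    c1 = extract_crop(IFFrame(ch), InstanceMask(lb), 1)
    assert np.array_equal(c0.data, c1.data)
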