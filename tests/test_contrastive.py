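"""Augmentation chain, NT-Xent loss vs double-loop oracle, encoder contracts."""

import numpy as np
import pytest

from lbxpheno.contrastive import (
    AugmentationConfig,
    ContrastiveEncoder,
    EncoderConfig,
    augment,
    make_view_pair,
    nt_xent_loss,
    _nt_xent_with_grad,
    train_encoder,
)
from lbxpheno.synthetic import generate_crop_dataset
from lbxpheno.types import LbxError


def nt_xent_oracle(z_pairs, tau):
    """Literal double-loop evaluation of the loss definition.

    Builds the explicit 2N x 2N cosine-similarity table and sums the
    normalized temperature-scaled cross-entropy term for every anchor.
    """
    z = np.asarray(z_pairs, dtype=float).reshape(-1, z_pairs.shape[-1])
    n2 = len(z)
    sim = np.zeros((n2, n2))
    for i in range(n2):
        for j in range(n2):
            sim[i, j] = z[i] @ z[j] / (np.linalg.norm(z[i]) * np.linalg.norm(z[j]))
    total = 0.0
    for i in range(n2):
        j = i + 1 if i % 2 == 0 else i - 1  # partner view
        denom = 0.0
        for k in range(n2):
            if k != i:
                denom += np.exp(sim[i, k] / tau)
        total += -np.log(np.exp(sim[i, j] / tau) / denom)
    return total / n2


# ---------------------------------------------------------------------------
# NT-Xent loss


@pytest.mark.parametrize("tau", [0.13, 0.5, 1.0])
def test_nt_xent_matches_double_loop_oracle(tau):
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(1, 17))
        d = int(rng.integers(2, 12))
        z = rng.standard_normal((n, 2, d))
        assert nt_xent_loss(z, tau) == pytest.approx(nt_xent_oracle(z, tau), abs=1e-6)


def test_nt_xent_single_pair_is_zero():
    rng = np.random.default_rng(0)
    for tau in (0.13, 1.0, 7.0):
        assert nt_xent_loss(rng.standard_normal((1, 2, 8)), tau) == 0.0


def test_nt_xent_two_orthogonal_pairs_closed_form():
    """Pairs (e1,e1), (e2,e2) at tau=1: every anchor term is -log(e/(e+2))."""
    e1 = np.array([1.0, 0, 0, 0])
    e2 = np.array([0, 1.0, 0, 0])
    z = np.stack([np.stack([e1, e1]), np.stack([e2, e2])])
    expected = -np.log(np.e / (np.e + 2 * np.exp(0.0)))
    assert nt_xent_loss(z, 1.0) == pytest.approx(expected, rel=1e-12)


def test_nt_xent_permutation_invariant():
    rng = np.random.default_rng(5)
    z = rng.standard_normal((8, 2, 6))
    base = nt_xent_loss(z, 0.13)
    for _ in range(5):
        perm = rng.permutation(8)
        assert nt_xent_loss(z[perm], 0.13) == pytest.approx(base, rel=1e-12)


def test_nt_xent_rotation_invariant():
    rng = np.random.default_rng(6)
    z = rng.standard_normal((6, 2, 8))
    q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
    zr = z @ q.T
    assert nt_xent_loss(zr, 0.13) == pytest.approx(nt_xent_loss(z, 0.13), rel=1e-9)


def test_nt_xent_decreases_with_positive_similarity():
    """With negatives fixed, aligning a positive pair lowers the loss."""
    rng = np.random.default_rng(7)
    neg = rng.standard_normal((5, 2, 8))
    a = np.zeros(8)
    a[0] = 1.0
    losses = []
    for angle in (1.2, 0.8, 0.4, 0.1):
        b = np.zeros(8)
        b[0], b[1] = np.cos(angle), np.sin(angle)
        z = np.concatenate([np.stack([a, b])[None], neg])
        losses.append(nt_xent_loss(z, 0.5))
    assert all(x > y for x, y in zip(losses, losses[1:]))


def test_nt_xent_zero_vector_errors():
    z = np.zeros((2, 2, 4))
    with pytest.raises(LbxError, match="zero-norm"):
        nt_xent_loss(z, 0.13)


def test_nt_xent_gradient_matches_finite_differences():
    rng = np.random.default_rng(8)
    z = rng.standard_normal((4, 2, 6))
    loss, dz = _nt_xent_with_grad(z, 0.13)
    eps = 1e-6
    for idx in [(0, 0, 0), (1, 1, 3), (3, 0, 5)]:
        zp = z.copy()
        zp[idx] += eps
        lp, _ = _nt_xent_with_grad(zp, 0.13)
        zp[idx] -= 2 * eps
        lm, _ = _nt_xent_with_grad(zp, 0.13)
        assert dz[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)


# ---------------------------------------------------------------------------
# augmentation chain


@pytest.fixture(scope="module")
def one_crop():
    crops, _ = generate_crop_dataset(1, phenotypes=("CTC",), seed=55)
    return crops[0]


def test_augment_all_probabilities_zero_is_identity(one_crop):
    rng = np.random.default_rng(0)
    out = augment(one_crop, AugmentationConfig.none(), rng)
    assert np.array_equal(out, one_crop)


def test_horizontal_flip_preserves_histograms_and_is_involution(one_crop):
    cfg = AugmentationConfig.none()
    cfg.p_hflip = 1.0
    rng = np.random.default_rng(0)
    once = augment(one_crop, cfg, rng)
    assert not np.array_equal(once, one_crop)
    for c in range(5):
        assert np.array_equal(np.sort(once[c], axis=None), np.sort(one_crop[c], axis=None))
    twice = augment(once, cfg, np.random.default_rng(1))
    assert np.array_equal(twice, one_crop)


def test_augment_seeded_determinism(one_crop):
    cfg = AugmentationConfig()
    a = augment(one_crop, cfg, np.random.default_rng(42))
    b = augment(one_crop, cfg, np.random.default_rng(42))
    c = augment(one_crop, cfg, np.random.default_rng(43))
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_augment_output_contract(one_crop):
    cfg = AugmentationConfig()
    rng = np.random.default_rng(3)
    for _ in range(20):
        out = augment(one_crop, cfg, rng)
        assert out.shape == (5, 75, 75)
        assert out.dtype == np.uint16
        assert set(np.unique(out[4])) <= {0, 1}


def test_photometric_stages_leave_mask_untouched(one_crop):
    cfg = AugmentationConfig.none()
    cfg.p_jitter = 1.0
    cfg.p_blur = 1.0
    rng = np.random.default_rng(4)
    out = augment(one_crop, cfg, rng)
    assert np.array_equal(out[4], one_crop[4])
    assert not np.array_equal(out[:4], one_crop[:4])


def test_make_view_pair(one_crop):
    cfg = AugmentationConfig()
    v1, v2 = make_view_pair(one_crop, cfg, np.random.default_rng(9))
    assert v1.shape == v2.shape == (5, 75, 75)
    assert not np.array_equal(v1, v2)
    r1, r2 = make_view_pair(one_crop, AugmentationConfig.none(), np.random.default_rng(9))
    assert np.array_equal(r1, one_crop) and np.array_equal(r2, one_crop)


def test_malformed_augmentation_config_errors():
    with pytest.raises(LbxError):
        AugmentationConfig(p_rotate=1.5)
    with pytest.raises(LbxError):
        AugmentationConfig(blur_sigma=(3.0, 0.5))


# ---------------------------------------------------------------------------
# encoder


@pytest.fixture(scope="module")
def tiny_crops():
    crops, labels = generate_crop_dataset(
        25, phenotypes=("CTC", "Lymph", "CEC", "Gran"), seed=77
    )
    return crops, labels


@pytest.fixture(scope="module")
def tiny_model(tiny_crops):
    crops, _ = tiny_crops
    model, trace = train_encoder(
        crops, EncoderConfig(epochs=3, batch_size=32), AugmentationConfig(), seed=5
    )
    return model, trace


def test_training_decreases_loss(tiny_model):
    _, trace = tiny_model
    assert trace[-1] < trace[0]


def test_encode_contract(tiny_model, tiny_crops):
    model, _ = tiny_model
    crops, _ = tiny_crops
    h = model.encode(crops[:10])
    assert h.values.shape == (10, 128)
    assert h.space == "learned-128"
    assert np.isfinite(h.values).all()
    # duplicates in a batch produce identical rows
    dup = np.concatenate([crops[:1], crops[:1]])
    hd = model.encode(dup)
    assert np.array_equal(hd.values[0], hd.values[1])


def test_encode_batch_size_independent(tiny_model, tiny_crops):
    model, _ = tiny_model
    crops, _ = tiny_crops
    full = model.encode(crops[:9], batch_size=9).values
    single = np.concatenate(
        [model.encode(crops[i : i + 1]).values for i in range(9)]
    )
    np.testing.assert_allclose(single, full, atol=1e-5)


def test_positive_pairs_more_similar_than_random_after_training(tiny_model, tiny_crops):
    model, _ = tiny_model
    crops, _ = tiny_crops
    cfg = AugmentationConfig()
    rng = np.random.default_rng(11)
    views = [make_view_pair(c, cfg, rng) for c in crops[:40]]
    h1 = model.encode(np.stack([v[0] for v in views])).values
    h2 = model.encode(np.stack([v[1] for v in views])).values

    def cos(a, b):
        return (a * b).sum(1) / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))

    pos = cos(h1, h2).mean()
    perm = np.random.default_rng(12).permutation(len(h2))
    rand = cos(h1, h2[perm]).mean()
    assert pos > rand


def test_project_maps_to_64(tiny_model):
    model, _ = tiny_model
    z = model.project(np.ones((3, 128), dtype=np.float32))
    assert z.shape == (3, 64)
    assert np.isfinite(z).all()
    with pytest.raises(LbxError):
        model.project(np.ones((3, 64)))


def test_train_seeded_determinism(tiny_crops):
    crops, _ = tiny_crops
    cfg = EncoderConfig(epochs=2, batch_size=32)
    _, t1 = train_encoder(crops[:48], cfg, AugmentationConfig(), seed=3)
    _, t2 = train_encoder(crops[:48], cfg, AugmentationConfig(), seed=3)
    assert t1 == t2


def test_encoder_save_load_roundtrip(tmp_path, tiny_model, tiny_crops):
    model, _ = tiny_model
    crops, _ = tiny_crops
    path = tmp_path / "enc.npz"
    model.save(path)
    loaded = ContrastiveEncoder.load(path)
    np.testing.assert_allclose(
        loaded.encode(crops[:5]).values, model.encode(crops[:5]).values, atol=1e-6
    )


def test_encoder_config_validation():
    with pytest.raises(LbxError):
        EncoderConfig(widths=(16, 32, 64, 64))
    with pytest.raises(LbxError):
        EncoderConfig(temperature=0.0)
    with pytest.raises(LbxError):
        EncoderConfig(batch_size=1)
    paper = EncoderConfig.paper()
    assert paper.batch_size == 1024 and paper.epochs == 50
    assert paper.temperature == 0.13 and paper.weight_decay == 1e-4
    # warm-up schedule: linear from 1e-3 to 1e-2 over 10 epochs, then flat
    assert paper.lr_at(0) == pytest.approx(1e-3)
    assert paper.lr_at(5) == pytest.approx(5.5e-3)
    assert paper.lr_at(10) == paper.lr_at(40) == pytest.approx(1e-2)
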