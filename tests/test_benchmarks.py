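"""Benchmark suite: probes, perturbations, clustering metrics vs longhand oracles."""

import numpy as np
import pytest

from lbxpheno.benchmarks import (
    PerturbationSpec,
    cluster,
    clustering_metrics,
    cosine_drift,
    enumerate_slides,
    imbalance_sweep,
    linear_probe,
    perturb,
    robustness_report,
    subsample_imbalance,
    train_enumerator,
)
from lbxpheno.synthetic import generate_crop_dataset
from lbxpheno.types import LbxError

# ---------------------------------------------------------------------------
# longhand clustering-metric oracles (pair counting + entropy sums)


def _oracle_metrics(pred, true):
    pred = np.asarray(pred)
    true = np.asarray(true)
    n = len(pred)
    # exhaustive pair counting for the Rand statistics
    a = b = c = d = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_t = true[i] == true[j]
            same_p = pred[i] == pred[j]
            if same_t and same_p:
                a += 1
            elif same_t and not same_p:
                c += 1
            elif not same_t and same_p:
                d += 1
            else:
                b += 1
    total = a + b + c + d
    exp_idx = (a + c) * (a + d) / total
    max_idx = ((a + c) + (a + d)) / 2
    ari = (a - exp_idx) / (max_idx - exp_idx) if max_idx != exp_idx else 1.0

    def entropy(labels):
        _, cnt = np.unique(labels, return_counts=True)
        p = cnt / n
        return float(-(p * np.log(p)).sum())

    def mutual_info(x, y):
        mi = 0.0
        for ux in np.unique(x):
            for uy in np.unique(y):
                pxy = np.mean((x == ux) & (y == uy))
                if pxy > 0:
                    px = np.mean(x == ux)
                    py = np.mean(y == uy)
                    mi += pxy * np.log(pxy / (px * py))
        return mi

    ht, hp = entropy(true), entropy(pred)
    mi = mutual_info(true, pred)
    # arithmetic-mean normalization (the scikit-learn default)
    nmi = 2 * mi / (ht + hp) if ht + hp > 0 else 1.0
    homogeneity = 1.0 if ht == 0 else mi / ht
    completeness = 1.0 if hp == 0 else mi / hp
    return dict(ari=ari, nmi=nmi, homogeneity=homogeneity, completeness=completeness)


def test_clustering_metrics_match_longhand_oracle():
    rng = np.random.default_rng(21)
    for _ in range(100):
        n = int(rng.integers(10, 200))
        true = rng.integers(0, rng.integers(2, 6), n)
        pred = rng.integers(0, rng.integers(2, 6), n)
        got = clustering_metrics(pred, true)
        want = _oracle_metrics(pred, true)
        for k in got:
            assert got[k] == pytest.approx(want[k], abs=1e-9), k


def test_clustering_metrics_definitional_identities():
    true = np.array([0, 0, 1, 1, 2, 2])
    relabeled = np.array([5, 5, 9, 9, 7, 7])
    m = clustering_metrics(relabeled, true)
    assert all(v == pytest.approx(1.0) for v in m.values())
    single = np.zeros(6, dtype=int)
    m1 = clustering_metrics(single, true)
    assert m1["homogeneity"] == pytest.approx(0.0)
    assert m1["completeness"] == pytest.approx(1.0)


def test_clustering_metrics_fixed_contingency_table():
    """3x2 table written out longhand: true classes x predicted clusters."""
    # counts: true A -> (3, 1), true B -> (0, 4), true C -> (2, 0)
    true = np.array(["A"] * 4 + ["B"] * 4 + ["C"] * 2)
    pred = np.array([0, 0, 0, 1, 1, 1, 1, 1, 0, 0])
    got = clustering_metrics(pred, true)
    want = _oracle_metrics(pred, true)
    for k in got:
        assert got[k] == pytest.approx(want[k], abs=1e-12)


def test_clustering_metrics_errors():
    with pytest.raises(LbxError):
        clustering_metrics([0, 1], [0])
    with pytest.raises(LbxError):
        clustering_metrics([0], [0])


# ---------------------------------------------------------------------------
# linear probe


def test_probe_perfect_features_reach_full_accuracy():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 5, 400)
    onehot = np.zeros((400, 16))
    onehot[np.arange(400), y] = 1.0
    res = linear_probe(onehot, y, split_seed=0)
    assert res.accuracy == 1.0
    assert res.roc_auc_macro == pytest.approx(1.0)
    assert (res.per_class["f1"] == 1.0).all()


def test_probe_noise_features_are_chance_level():
    rng = np.random.default_rng(2)
    accs = []
    for seed in range(5):
        x = rng.standard_normal((1000, 20))
        y = np.repeat(np.arange(10), 100)
        accs.append(linear_probe(x, y, split_seed=seed).accuracy)
    assert abs(np.mean(accs) - 0.1) < 0.05


def test_probe_split_is_stratified_80_20():
    y = np.repeat(np.arange(4), 50)
    x = np.zeros((200, 3))
    res = linear_probe(x + np.random.default_rng(0).standard_normal((200, 3)), y)
    # held-out support: 20% of each class
    assert res.per_class["support"].tolist() == [10, 10, 10, 10]


def test_probe_errors():
    x = np.zeros((10, 2))
    with pytest.raises(LbxError):
        linear_probe(x, np.zeros(10))
    with pytest.raises(LbxError):
        linear_probe(x, np.array([0] * 9 + [1]))


# ---------------------------------------------------------------------------
# perturbations and drift


@pytest.fixture(scope="module")
def crop():
    crops, _ = generate_crop_dataset(1, phenotypes=("CTC",), seed=41)
    return crops[0]


def test_perturb_identity_limits(crop):
    assert np.array_equal(perturb(crop, PerturbationSpec("intensity_scale", 1.0)), crop)
    assert np.array_equal(perturb(crop, PerturbationSpec("gaussian_blur", 0.0)), crop)
    near = perturb(crop, PerturbationSpec("resize", 1.0))
    assert np.array_equal(near, crop)


def test_perturb_magnitude_ranges_enforced():
    with pytest.raises(LbxError):
        PerturbationSpec("intensity_scale", 1.5)
    with pytest.raises(LbxError):
        PerturbationSpec("resize", 0.5)
    with pytest.raises(LbxError):
        PerturbationSpec("gaussian_blur", -1.0)
    with pytest.raises(LbxError):
        PerturbationSpec("warp", 1.0)


def test_blur_and_intensity_leave_mask_untouched(crop):
    for spec in (
        PerturbationSpec("gaussian_blur", 2.0),
        PerturbationSpec("intensity_scale", 1.2),
        PerturbationSpec("intensity_scale", 0.8, channel=1),
    ):
        out = perturb(crop, spec)
        assert np.array_equal(out[4], crop[4])


def test_intensity_scale_targets_one_channel(crop):
    out = perturb(crop, PerturbationSpec("intensity_scale", 1.2, channel=2))
    assert not np.array_equal(out[2], crop[2])
    for c in (0, 1, 3):
        assert np.array_equal(out[c], crop[c])


def test_resize_constant_interior_preserved():
    const = np.full((5, 75, 75), 20000, dtype=np.uint16)
    const[4] = 0
    const[4, 20:55, 20:55] = 1
    out = perturb(const, PerturbationSpec("resize", 1.1))
    # away from borders the constant intensity is unchanged
    assert np.array_equal(out[:4, 10:65, 10:65], const[:4, 10:65, 10:65])
    assert out.shape == (5, 75, 75)


def test_cosine_drift_values():
    v = np.array([1.0, 0.0])
    w = np.array([0.0, 1.0])
    assert cosine_drift(v, v)[0] == pytest.approx(0.0)
    assert cosine_drift(v, w)[0] == pytest.approx(1.0)
    assert cosine_drift(v, 2 * v)[0] == pytest.approx(0.0)
    with pytest.raises(LbxError):
        cosine_drift(v, np.zeros(2))


def test_robustness_report_zero_magnitude_and_blur_monotonicity():
    crops, _ = generate_crop_dataset(8, phenotypes=("CTC", "Lymph"), seed=43)
    from lbxpheno.features import engineered_features_batch

    extractors = {
        "engineered": lambda c: engineered_features_batch(c).values,
        "raw-mean": lambda c: c[:, :4].astype(float).mean(axis=(2, 3)),
    }
    specs = [PerturbationSpec("gaussian_blur", s) for s in (0.0, 0.5, 1.0, 2.0)]
    rep = robustness_report(crops, extractors, specs)
    z = rep[(rep.magnitude == 0.0)]
    assert (z.mean_drift.abs() < 1e-12).all()
    eng = rep[rep.space == "engineered"].sort_values("magnitude")
    drifts = eng.mean_drift.to_numpy()
    assert all(a <= b + 1e-12 for a, b in zip(drifts, drifts[1:]))
    with pytest.raises(LbxError):
        robustness_report(crops, {"only-one": extractors["raw-mean"]}, specs)


# ---------------------------------------------------------------------------
# imbalance subsampling and clustering


def test_subsample_counts_and_determinism():
    y = np.array(["rare"] * 100 + ["imm"] * 500)
    is_rare = y == "rare"
    idx = subsample_imbalance(y, is_rare, 2.0, seed=3)
    assert is_rare[idx].sum() == 100
    assert (~is_rare[idx]).sum() == 200
    idx2 = subsample_imbalance(y, is_rare, 2.0, seed=3)
    np.testing.assert_array_equal(idx, idx2)
    with pytest.raises(LbxError, match="max feasible"):
        subsample_imbalance(y, is_rare, 6.0)
    with pytest.raises(LbxError):
        subsample_imbalance(y, is_rare, 0.1)


def test_kmeans_separable_blobs_perfect_split():
    rng = np.random.default_rng(31)
    a = rng.standard_normal((80, 6)) + 8
    b = rng.standard_normal((80, 6)) - 8
    x = np.vstack([a, b])
    y = np.array([0] * 80 + [1] * 80)
    pred = cluster(x, "kmeans", n_clusters=2, seed=0)
    assert clustering_metrics(pred, y)["ari"] == 1.0


def test_leiden_identical_points_single_cluster():
    x = np.zeros((40, 4)) + 1.0
    x += np.random.default_rng(0).standard_normal((40, 4)) * 1e-9
    pred = cluster(x, "leiden", seed=0, scale=None)
    assert len(np.unique(pred)) <= 2


def test_cluster_seeded_determinism():
    rng = np.random.default_rng(33)
    x = rng.standard_normal((120, 8))
    for method in ("kmeans", "leiden"):
        p1 = cluster(x, method, seed=4)
        p2 = cluster(x, method, seed=4)
        np.testing.assert_array_equal(p1, p2)


def test_cluster_too_few_points_errors():
    x = np.zeros((5, 3))
    with pytest.raises(LbxError):
        cluster(x, "kmeans")
    with pytest.raises(LbxError):
        cluster(x, "leiden")
    with pytest.raises(LbxError):
        cluster(x, "dbscan")


def test_imbalance_sweep_shared_rare_set():
    rng = np.random.default_rng(35)
    x = np.vstack([rng.standard_normal((20, 4)) + 8, rng.standard_normal((300, 4))])
    y = np.array(["rare"] * 20 + ["imm"] * 300)
    rep = imbalance_sweep(x, y, y == "rare", ratios=(0.5, 2.0), methods=("kmeans",), seed=0)
    assert set(rep.ratio) == {0.5, 2.0}
    assert (rep.n == [20 + 10, 20 + 40]).all()
    assert ((rep[["ari", "nmi", "homogeneity", "completeness"]] >= -1).all()).all()


# ---------------------------------------------------------------------------
# enumeration


def test_enumerator_capacity_on_separable_features():
    rng = np.random.default_rng(51)
    x = rng.standard_normal((600, 128))
    y = np.array(["other"] * 500 + ["A"] * 60 + ["B"] * 40)
    x[y == "A", :10] += 4
    x[y == "B", 10:20] -= 4
    model = train_enumerator(x, y, "two-layer", seed=0)
    assert (model.predict(x) == y).mean() > 0.99


def test_enumerator_imbalance_stress():
    """Class imbalance like the contrived training profile still recovers
    the rare classes on held-out separable features (F1 > 0.9)."""
    rng = np.random.default_rng(52)

    def make(n_other, n_a, n_b, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal((n_other + n_a + n_b, 128))
        y = np.array(["other"] * n_other + ["A"] * n_a + ["B"] * n_b)
        x[y == "A", :8] += 3.5
        x[y == "B", 8:16] -= 3.5
        return x, y

    xtr, ytr = make(6600, 680, 410, 1)
    xte, yte = make(2000, 60, 40, 2)
    model = train_enumerator(xtr, ytr, "two-layer", seed=0)
    rep = enumerate_slides(model, {"s": xte}, {"s": yte})
    assert (rep.pooled_micro["f1"] > 0.9).all()


def test_enumerator_seeded_determinism():
    rng = np.random.default_rng(53)
    x = rng.standard_normal((200, 128))
    y = np.array(["other"] * 150 + ["A"] * 50)
    x[y == "A"] += 2
    m1 = train_enumerator(x, y, "three-layer", seed=9, epochs=5)
    m2 = train_enumerator(x, y, "three-layer", seed=9, epochs=5)
    np.testing.assert_array_equal(m1.predict(x), m2.predict(x))


def test_enumerator_single_class_errors():
    x = np.zeros((20, 128))
    with pytest.raises(LbxError):
        train_enumerator(x, ["other"] * 20, "two-layer")
    with pytest.raises(LbxError):
        train_enumerator(x, ["other"] * 10 + ["A"] * 10, "four-layer")


def test_enumeration_report_formulas():
    """Toy confusion counts: TP=9, FP=1, FN=2 per the direct formulas."""
    y_true = np.array(["A"] * 11 + ["other"] * 10)
    y_pred = np.array(["A"] * 9 + ["other"] * 2 + ["A"] * 1 + ["other"] * 9)

    class Fixed:
        classes = np.array(["A", "other"])

        def predict(self, f):
            return y_pred

    rep = enumerate_slides(Fixed(), {"s": np.zeros((21, 1))}, {"s": y_true})
    row = rep.pooled_micro.iloc[0]
    assert row.precision == pytest.approx(0.9)
    assert row.recall == pytest.approx(9 / 11)
    assert row.f1 == pytest.approx(2 * 0.9 * (9 / 11) / (0.9 + 9 / 11))


def test_enumeration_always_other_zero_metrics_with_flag():
    y_true = np.array(["A"] * 5 + ["other"] * 15)

    class AlwaysOther:
        classes = np.array(["A", "other"])

        def predict(self, f):
            return np.array(["other"] * 20)

    rep = enumerate_slides(AlwaysOther(), {"s": np.zeros((20, 1))}, {"s": y_true})
    row = rep.pooled_micro.iloc[0]
    assert row.precision == 0.0 and row.recall == 0.0 and row.f1 == 0.0
    assert rep.undefined_precision


def test_enumeration_slide_mismatch_errors():
    class Dummy:
        classes = np.array(["A", "other"])

        def predict(self, f):
            return np.array(["other"] * len(f))

    with pytest.raises(LbxError):
        enumerate_slides(Dummy(), {"a": np.zeros((3, 1))}, {"b": ["other"] * 3})
    with pytest.raises(LbxError):
        enumerate_slides(Dummy(), {"a": np.zeros((3, 1))}, {"a": ["other"] * 4})
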