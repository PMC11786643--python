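import numpy as np
import pytest

from effconn import classify as clf
from effconn.errors import ConfigurationError, UndefinedMetricError, ValidationError

CLASSES = ["disgust", "fear", "happiness", "sadness"]

# distinct solid colors -> linearly separable image classes
_COLORS = {
    "disgust": (200, 30, 30),
    "fear": (30, 200, 30),
    "happiness": (30, 30, 200),
    "sadness": (180, 180, 30),
}


def _solid_dataset(per_class=25, size=35, jitter=10, seed=0, subjects=None):
    rng = np.random.default_rng(seed)
    out = []
    for label in CLASSES:
        base = np.array(_COLORS[label], dtype=float)
        for t in range(per_class):
            px = base + rng.integers(-jitter, jitter + 1, size=(size, size, 3))
            px = np.clip(px, 0, 255).astype(np.uint8)
            subject = None if subjects is None else f"s{t % subjects:02d}"
            out.append(clf.LabeledImage(pixels=px, label=label,
                                        id=f"{label}_{t:04d}", subject=subject))
    return out


class TestMakeFolds:
    def test_balanced_stratified(self):
        ds = _solid_dataset(per_class=25)
        split = clf.make_folds(ds, k=5, seed=1)
        counts = np.zeros((5, 4), dtype=int)
        for it in ds:
            counts[split.fold_of(it.id), CLASSES.index(it.label)] += 1
        assert np.all(counts == 5)

    def test_deterministic(self):
        ds = _solid_dataset(per_class=10)
        a = clf.make_folds(ds, k=5, seed=42)
        b = clf.make_folds(ds, k=5, seed=42)
        assert a.assignments == b.assignments

    def test_fold_sizes_differ_by_at_most_one(self):
        ds = _solid_dataset(per_class=13)  # 52 images, not divisible by 5
        split = clf.make_folds(ds, k=5, seed=3)
        sizes = np.bincount([split.fold_of(it.id) for it in ds], minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_subject_mode_grouping(self):
        ds = _solid_dataset(per_class=24, subjects=24)
        split = clf.make_folds(ds, k=5, mode="subject", seed=0)
        fold_by_subject = {}
        for it in ds:
            f = split.fold_of(it.id)
            assert fold_by_subject.setdefault(it.subject, f) == f

    def test_insufficient_data(self):
        ds = _solid_dataset(per_class=3)
        with pytest.raises(ValidationError):
            clf.make_folds(ds, k=5)


class TestSmallCNN:
    def test_separable_classes_learned(self):
        ds = _solid_dataset(per_class=10, seed=1)
        handle = clf.SmallCNN(seed=0, epochs=5)
        handle.fit([it.pixels for it in ds], [it.label for it in ds])
        conf = clf.evaluate(handle, ds)
        assert np.trace(conf) == len(ds)  # training accuracy 1.0

    def test_proba_rows_sum_to_one(self):
        ds = _solid_dataset(per_class=8, seed=2)
        handle = clf.SmallCNN(seed=0, epochs=2)
        handle.fit([it.pixels for it in ds], [it.label for it in ds])
        probs = handle.predict_proba([it.pixels for it in ds[:7]])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.min() >= 0.0

    def test_deterministic_given_seed(self):
        ds = _solid_dataset(per_class=6, seed=3)
        imgs = [it.pixels for it in ds]
        labs = [it.label for it in ds]
        p1 = clf.SmallCNN(seed=7, epochs=2).fit(imgs, labs).predict_proba(imgs)
        p2 = clf.SmallCNN(seed=7, epochs=2).fit(imgs, labs).predict_proba(imgs)
        assert np.array_equal(p1, p2)


class TestTransferBackend:
    class _GoodNet:
        fc = object()

        def features(self, images):
            return np.array(
                [[im[..., 0].mean() / 255, im[..., 1].mean() / 255,
                  im[..., 2].mean() / 255, 1.0] for im in images])

    class _HeadlessNet:
        def features(self, images):  # no fc / classifier attribute
            return np.zeros((len(images), 4))

    def test_rejects_headless_network(self):
        with pytest.raises(ConfigurationError, match="fully connected"):
            clf.TransferAdapter(self._HeadlessNet())

    def test_rejects_featureless_network(self):
        with pytest.raises(ConfigurationError, match="features"):
            clf.TransferAdapter(object())

    def test_head_finetune_learns(self):
        ds = _solid_dataset(per_class=10, seed=4)
        handle = clf.TransferAdapter(self._GoodNet(), seed=0, epochs=30)
        handle.fit([it.pixels for it in ds], [it.label for it in ds])
        probs = handle.predict_proba([it.pixels for it in ds])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        conf = clf.evaluate(handle, ds)
        # features separate color classes; head should find most of it
        assert np.trace(conf) >= 0.7 * len(ds)


class TestTrainClassifier:
    def test_missing_class_error(self):
        ds = [it for it in _solid_dataset(per_class=6) if it.label != "fear"]
        with pytest.raises(ValidationError, match="fear"):
            clf.train_classifier(ds, clf.TrainConfig(epochs=1), classes=CLASSES)

    def test_unknown_backend(self):
        with pytest.raises(ConfigurationError):
            clf.TrainConfig(backend="resnet2000").build()


class TestEvaluate:
    class _Const:
        classes = CLASSES

        def predict_proba(self, images):
            p = np.zeros((len(images), 4))
            p[:, 2] = 1.0
            return p

    def test_constant_predictor_single_column(self):
        ds = _solid_dataset(per_class=5)
        conf = clf.evaluate(self._Const(), ds)
        assert conf[:, 2].sum() == len(ds)
        assert conf.sum() == len(ds)

    def test_empty_test_set(self):
        with pytest.raises(ValidationError):
            clf.evaluate(self._Const(), [])


class TestMetrics:
    def test_perfect_diagonal(self):
        conf = np.diag([10, 10, 10, 10])
        assert clf.average_accuracy(conf) == 1.0
        for i in range(4):
            assert clf.auc_ovr(conf, i) == 1.0

    def test_hand_example_average_accuracy(self):
        conf = np.array([[40, 10, 0, 0], [10, 40, 0, 0],
                         [0, 0, 50, 0], [0, 0, 0, 50]])
        assert clf.average_accuracy(conf) == pytest.approx(0.95)

    def test_hand_example_auc(self):
        # TP=40 FN=10 TN=140 FP=10 -> 0.5*(0.8 + 0.93333) = 0.86667
        conf = np.array([[40, 10, 0, 0], [4, 43, 0, 3],
                         [3, 0, 47, 0], [3, 0, 0, 47]])
        tp, fn, fp, tn = 40, 10, 10, 140
        assert clf.auc_ovr(conf, 0) == pytest.approx(
            0.5 * (tp / (tp + fn) + tn / (tn + fp)))
        assert clf.auc_ovr(conf, 0) == pytest.approx(0.8667, abs=1e-4)

    def test_random_predictor_expectations(self):
        # balanced 4-class, uniform predictions: Eq-6 accuracy -> 0.625, AUC -> 0.5
        rng = np.random.default_rng(0)
        n = 100_000
        true = rng.integers(0, 4, n)
        pred = rng.integers(0, 4, n)
        conf = np.zeros((4, 4), dtype=int)
        np.add.at(conf, (true, pred), 1)
        assert clf.average_accuracy(conf) == pytest.approx(0.625, abs=0.01)
        for i in range(4):
            assert clf.auc_ovr(conf, i) == pytest.approx(0.5, abs=0.01)

    def test_undefined_auc(self):
        conf = np.zeros((4, 4), dtype=int)
        conf[1, 1] = 5
        with pytest.raises(UndefinedMetricError):
            clf.auc_ovr(conf, 0)


class TestCrossValidate:
    def test_partition_and_metrics(self):
        ds = _solid_dataset(per_class=10, seed=5)
        res = clf.cross_validate(ds, k=5, config=clf.TrainConfig(epochs=10, seed=1),
                                 seed=1)
        assert sum(c.sum() for c in res.confusions) == len(ds)
        assert res.mean_accuracy > 0.9  # separable classes
        assert res.auc_per_class.shape == (5, 4)
        assert np.all(res.roc_auc_per_class <= 1.0)
        # report serializes
        assert "mean_accuracy" in res.to_json()

    def test_reproducible(self):
        ds = _solid_dataset(per_class=6, seed=6)
        cfg = clf.TrainConfig(epochs=2, seed=2)
        r1 = clf.cross_validate(ds, k=3, config=cfg, seed=2)
        r2 = clf.cross_validate(ds, k=3, config=cfg, seed=2)
        assert r1.to_json() == r2.to_json()
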