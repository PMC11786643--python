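"""Cross-validated 4-class classification of connectivity images.

The classifier backend is pluggable behind a fit/predict_proba contract.
Two backends ship: ``small_cnn``, a from-scratch 3-block convolutional
network (pure numpy, CPU-trainable in minutes), and ``transfer``, an adapter
that replaces the final fully connected layer of a user-supplied pretrained
feature network with a fresh 4-way softmax head and fine-tunes it with the
reference hyperparameters (Adam, lr 8e-4, batch 32, gradient decay 0.99,
up to 30 epochs, cross-entropy).

Metric conventions: ``average_accuracy`` is the mean one-vs-rest accuracy
over the 4 classes, so a random predictor on balanced data scores ~0.625,
not 0.25. ``auc_ovr`` is 0.5*(sensitivity+specificity) of the hard
classifier — algebraically balanced accuracy, not ROC area; a conventional
probability-ranking ROC-AUC is additionally reported by cross_validate.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import ConfigurationError, UndefinedMetricError, ValidationError
from .imaging import ConnectivityImage


@dataclass
class LabeledImage:
    pixels: np.ndarray  # (H, W, 3) uint8
    label: str
    id: str
    subject: str | None = None


def as_labeled_images(images: list[ConnectivityImage]) -> list[LabeledImage]:
    """Adapt rendered ConnectivityImages (with emotion metadata) to the dataset type."""
    out = []
    for k, img in enumerate(images):
        label = img.meta.get("emotion")
        if label in (None, "None"):
            raise ValidationError(f"image {k} has no emotion label")
        out.append(
            LabeledImage(
                pixels=img.pixels, label=str(label), id=f"img{k:06d}",
                subject=img.meta.get("subject_id"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# fold construction

@dataclass
class FoldSplit:
    k: int
    assignments: dict[str, int]  # image id -> fold index
    mode: str
    seed: int

    def fold_of(self, image_id: str) -> int:
        return self.assignments[image_id]


def make_folds(dataset: list[LabeledImage], k: int = 5, mode: str = "window",
               seed: int = 0) -> FoldSplit:
    """Stratified (window mode) or subject-grouped fold assignment."""
    if mode not in ("window", "subject"):
        raise ValidationError(f"unknown fold mode {mode!r}")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}

    if mode == "window":
        by_class: dict[str, list[LabeledImage]] = {}
        for item in dataset:
            by_class.setdefault(item.label, []).append(item)
        for label, items in sorted(by_class.items()):
            if len(items) < k:
                raise ValidationError(
                    f"class {label!r} has {len(items)} images; need >= {k} per class"
                )
        counts = np.zeros(k, dtype=int)
        for label in sorted(by_class):
            items = sorted(by_class[label], key=lambda it: it.id)
            rng.shuffle(items)
            # fill the currently least-loaded folds first; round-robin within class
            order = np.argsort(counts, kind="stable")
            for pos, item in enumerate(items):
                f = int(order[pos % k])
                assignments[item.id] = f
                counts[f] += 1
    else:
        subjects = sorted({it.subject for it in dataset if it.subject is not None})
        if len(subjects) < k:
            raise ValidationError(f"{len(subjects)} subjects; need >= {k} for subject folds")
        per_subject: dict[str, int] = {}
        for it in dataset:
            if it.subject is None:
                raise ValidationError(f"image {it.id} lacks a subject id in subject mode")
            per_subject[it.subject] = per_subject.get(it.subject, 0) + 1
        shuffled = list(subjects)
        rng.shuffle(shuffled)
        # largest subjects first onto the emptiest fold
        shuffled.sort(key=lambda s: -per_subject[s])
        counts = np.zeros(k, dtype=int)
        sub_fold: dict[str, int] = {}
        for s in shuffled:
            f = int(np.argmin(counts))
            sub_fold[s] = f
            counts[f] += per_subject[s]
        for it in dataset:
            assignments[it.id] = sub_fold[it.subject]

    return FoldSplit(k=k, assignments=assignments, mode=mode, seed=seed)


# ---------------------------------------------------------------------------
# numpy CNN primitives

def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3, pad-1 patches: (N, C, H, W) -> (N, C*9, H*W)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, 9, h, w), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di : di + h, dj : dj + w]
            k += 1
    return cols.reshape(n, c * 9, h * w)


def _col2im(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of _im2col."""
    n, c, h, w = shape
    d = dcols.reshape(n, c, 9, h, w)
    out = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            out[:, :, di : di + h, dj : dj + w] += d[:, :, k]
            k += 1
    return out[:, :, 1 : 1 + h, 1 : 1 + w]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _resize_nearest(pixels: np.ndarray, size: int) -> np.ndarray:
    h, w = pixels.shape[:2]
    ri = (np.arange(size) * h) // size
    ci = (np.arange(size) * w) // size
    return pixels[np.ix_(ri, ci)]


class SmallCNN:
    """Three conv blocks (8, 16, 32 channels; 3x3 kernels; 2x2 average pooling
    after the first two) followed by a linear softmax layer. Trained with Adam
    on cross-entropy. Inputs are nearest-resized to ``input_size``."""

    def __init__(self, seed: int = 0, epochs: int = 15, lr: float = 1e-3,
                 batch_size: int = 32, input_size: int = 36):
        self.seed = seed
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.input_size = input_size
        self.classes: list[str] = []
        self._params: list[np.ndarray] | None = None

    # -- plumbing

    def _prep(self, images: list[np.ndarray]) -> np.ndarray:
        out = np.empty((len(images), 3, self.input_size, self.input_size))
        for k, px in enumerate(images):
            r = _resize_nearest(np.asarray(px), self.input_size)
            out[k] = r.transpose(2, 0, 1) / 255.0 - 0.5
        return out

    def _init_params(self, rng: np.random.Generator) -> list[np.ndarray]:
        def he(fan_in, *shape):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        s = self.input_size // 4  # after two 2x2 pools
        d = 32 * s * s
        return [
            he(3 * 9, 8, 3 * 9), np.zeros(8),        # conv1
            he(8 * 9, 16, 8 * 9), np.zeros(16),      # conv2
            he(16 * 9, 32, 16 * 9), np.zeros(32),    # conv3
            he(d, 4, d), np.zeros(4),                # fc
        ]

    @staticmethod
    def _conv(x, W, b):
        n, _, h, w = x.shape
        cols = _im2col(x)
        out = np.einsum("fk,nkp->nfp", W, cols) + b[None, :, None]
        return out.reshape(n, W.shape[0], h, w), cols

    @staticmethod
    def _pool(x):
        n, c, h, w = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    @staticmethod
    def _unpool(d):
        return np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) / 4.0

    def _forward(self, x, params, cache=False):
        W1, b1, W2, b2, W3, b3, Wf, bf = params
        z1, c1 = self._conv(x, W1, b1)
        a1 = np.maximum(z1, 0)
        p1 = self._pool(a1)
        z2, c2 = self._conv(p1, W2, b2)
        a2 = np.maximum(z2, 0)
        p2 = self._pool(a2)
        z3, c3 = self._conv(p2, W3, b3)
        a3 = np.maximum(z3, 0)
        flat = a3.reshape(x.shape[0], -1)
        logits = flat @ Wf.T + bf
        if not cache:
            return logits, None
        return logits, (x, c1, z1, p1, c2, z2, p2, c3, z3, a3, flat)

    def _backward(self, dlogits, cache, params):
        W1, b1, W2, b2, W3, b3, Wf, bf = params
        x, c1, z1, p1, c2, z2, p2, c3, z3, a3, flat = cache
        dWf = dlogits.T @ flat
        dbf = dlogits.sum(axis=0)
        da3 = (dlogits @ Wf).reshape(a3.shape)
        dz3 = da3 * (z3 > 0)
        n, f3, h3, w3 = dz3.shape
        dz3f = dz3.reshape(n, f3, h3 * w3)
        dW3 = np.einsum("nfp,nkp->fk", dz3f, c3)
        db3 = dz3f.sum(axis=(0, 2))
        dp2 = _col2im(np.einsum("fk,nfp->nkp", W3, dz3f), p2.shape)
        dz2 = self._unpool(dp2) * (z2 > 0)
        n, f2, h2, w2 = dz2.shape
        dz2f = dz2.reshape(n, f2, h2 * w2)
        dW2 = np.einsum("nfp,nkp->fk", dz2f, c2)
        db2 = dz2f.sum(axis=(0, 2))
        dp1 = _col2im(np.einsum("fk,nfp->nkp", W2, dz2f), p1.shape)
        dz1 = self._unpool(dp1) * (z1 > 0)
        n, f1, h1, w1 = dz1.shape
        dz1f = dz1.reshape(n, f1, h1 * w1)
        dW1 = np.einsum("nfp,nkp->fk", dz1f, c1)
        db1 = dz1f.sum(axis=(0, 2))
        return [dW1, db1, dW2, db2, dW3, db3, dWf, dbf]

    # -- public contract

    def fit(self, images: list[np.ndarray], labels: list[str]) -> "SmallCNN":
        if len(images) == 0:
            raise ValidationError("empty training set")
        self.classes = sorted(set(labels))
        y = np.array([self.classes.index(l) for l in labels])
        x = self._prep(images)
        rng = np.random.default_rng(self.seed)
        params = self._init_params(rng)
        opt = _Adam(params, lr=self.lr)
        n = len(images)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                logits, cache = self._forward(x[idx], params, cache=True)
                probs = _softmax(logits)
                d = probs.copy()
                d[np.arange(len(idx)), y[idx]] -= 1.0
                d /= len(idx)
                opt.step(self._backward(d, cache, params))
        self._params = params
        return self

    def predict_proba(self, images: list[np.ndarray]) -> np.ndarray:
        if self._params is None:
            raise ValidationError("classifier not fitted")
        x = self._prep(images)
        out = []
        for s in range(0, len(images), 256):
            logits, _ = self._forward(x[s : s + 256], self._params)
            out.append(_softmax(logits))
        return np.vstack(out)


class TransferAdapter:
    """Wrap a user-supplied pretrained network: replace its final fully
    connected layer with a fresh 4-way softmax head and fine-tune the head.

    The network must expose ``features(images) -> (N, D)`` and carry its
    original final fully connected layer as attribute ``fc`` or
    ``classifier``. Only the replaced head is trained here (framework-free
    linear fine-tune); hyperparameters follow the reference setup.
    """

    def __init__(self, network, seed: int = 0, epochs: int = 30, lr: float = 8e-4,
                 batch_size: int = 32, grad_decay: float = 0.99):
        if not callable(getattr(network, "features", None)):
            raise ConfigurationError(
                "pretrained network must expose a features(images) method"
            )
        if getattr(network, "fc", None) is None and getattr(network, "classifier", None) is None:
            raise ConfigurationError(
                "pretrained network has no final fully connected layer "
                "('fc' or 'classifier' attribute); cannot adapt"
            )
        self.network = network
        self.seed, self.epochs, self.lr = seed, epochs, lr
        self.batch_size, self.grad_decay = batch_size, grad_decay
        self.classes: list[str] = []
        self._W: np.ndarray | None = None
        self._b: np.ndarray | None = None

    def fit(self, images, labels) -> "TransferAdapter":
        if len(images) == 0:
            raise ValidationError("empty training set")
        self.classes = sorted(set(labels))
        y = np.array([self.classes.index(l) for l in labels])
        feats = np.asarray(self.network.features(images), dtype=float)
        rng = np.random.default_rng(self.seed)
        d = feats.shape[1]
        W = rng.standard_normal((len(self.classes), d)) * 0.01
        b = np.zeros(len(self.classes))
        opt = _Adam([W, b], lr=self.lr, beta1=self.grad_decay)
        n = len(images)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                probs = _softmax(feats[idx] @ W.T + b)
                dlog = probs
                dlog[np.arange(len(idx)), y[idx]] -= 1.0
                dlog /= len(idx)
                opt.step([dlog.T @ feats[idx], dlog.sum(axis=0)])
        self._W, self._b = W, b
        return self

    def predict_proba(self, images) -> np.ndarray:
        if self._W is None:
            raise ValidationError("classifier not fitted")
        feats = np.asarray(self.network.features(images), dtype=float)
        return _softmax(feats @ self._W.T + self._b)


@dataclass
class TrainConfig:
    backend: str = "small_cnn"
    epochs: int = 15
    lr: float = 1e-3
    batch_size: int = 32
    input_size: int = 36
    seed: int = 0
    network: object | None = None  # pretrained network for the transfer backend

    def build(self, seed: int | None = None):
        s = self.seed if seed is None else seed
        if self.backend == "small_cnn":
            return SmallCNN(seed=s, epochs=self.epochs, lr=self.lr,
                            batch_size=self.batch_size, input_size=self.input_size)
        if self.backend == "transfer":
            if self.network is None:
                raise ConfigurationError("transfer backend needs a pretrained network")
            return TransferAdapter(self.network, seed=s, epochs=self.epochs,
                                   batch_size=self.batch_size)
        raise ConfigurationError(f"unknown backend {self.backend!r}")


def train_classifier(train_set: list[LabeledImage], config: TrainConfig,
                     classes: list[str] | None = None, seed: int | None = None):
    """Fit a backend on the training images; all `classes` must be present."""
    if not train_set:
        raise ValidationError("empty training set")
    present = sorted({it.label for it in train_set})
    expected = sorted(classes) if classes is not None else present
    missing = set(expected) - set(present)
    if missing:
        raise ValidationError(f"training data misses classes: {sorted(missing)}")
    handle = config.build(seed=seed)
    handle.fit([it.pixels for it in train_set], [it.label for it in train_set])
    return handle


def evaluate(handle, test_set: list[LabeledImage]) -> np.ndarray:
    """Confusion matrix (rows = true class, columns = predicted), class order
    = handle.classes."""
    if not test_set:
        raise ValidationError("empty test set")
    classes = handle.classes
    probs = handle.predict_proba([it.pixels for it in test_set])
    pred = probs.argmax(axis=1)
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for it, p in zip(test_set, pred):
        conf[classes.index(it.label), p] += 1
    return conf


# ---------------------------------------------------------------------------
# metrics

def _ovr_counts(confusion: np.ndarray, i: int) -> tuple[int, int, int, int]:
    conf = np.asarray(confusion)
    tp = conf[i, i]
    fn = conf[i].sum() - tp
    fp = conf[:, i].sum() - tp
    tn = conf.sum() - tp - fn - fp
    return int(tp), int(fn), int(fp), int(tn)


def average_accuracy(confusion: np.ndarray) -> float:
    """Mean one-vs-rest accuracy over classes: avg_i (tp_i+tn_i)/N."""
    conf = np.asarray(confusion)
    if conf.sum() == 0:
        raise ValidationError("empty confusion matrix")
    total = conf.sum()
    accs = []
    for i in range(conf.shape[0]):
        tp, fn, fp, tn = _ovr_counts(conf, i)
        accs.append((tp + tn) / total)
    return float(np.mean(accs))


def auc_ovr(confusion: np.ndarray, positive_class: int) -> float:
    """0.5 * (sensitivity + specificity) for one class vs the rest."""
    tp, fn, fp, tn = _ovr_counts(confusion, positive_class)
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError(
            f"class {positive_class}: no positives or no negatives in the test set"
        )
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


@dataclass
class ClassificationResult:
    classes: list[str]
    confusions: list[np.ndarray]  # per fold
    fold_accuracies: list[float]  # Eq-6 style average accuracy per fold
    mean_accuracy: float
    std_accuracy: float
    auc_per_class: np.ndarray  # (k, n_classes) hard balanced-accuracy AUC
    roc_auc_per_class: np.ndarray  # (k, n_classes) probability-ranking ROC AUC
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": self.classes,
                "confusions": [c.tolist() for c in self.confusions],
                "fold_accuracies": self.fold_accuracies,
                "mean_accuracy": self.mean_accuracy,
                "std_accuracy": self.std_accuracy,
                "auc_per_class": self.auc_per_class.tolist(),
                "roc_auc_per_class": self.roc_auc_per_class.tolist(),
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )


def cross_validate(dataset: list[LabeledImage], k: int = 5,
                   config: TrainConfig | None = None, mode: str = "window",
                   seed: int = 0) -> ClassificationResult:
    """k-fold CV: train on k-1 folds, test on the held-out fold, aggregate."""
    config = config or TrainConfig()
    classes = sorted({it.label for it in dataset})
    split = make_folds(dataset, k=k, mode=mode, seed=seed)
    confusions, accs = [], []
    aucs = np.zeros((k, len(classes)))
    rocs = np.zeros((k, len(classes)))
    for f in range(k):
        train = [it for it in dataset if split.fold_of(it.id) != f]
        test = [it for it in dataset if split.fold_of(it.id) == f]
        handle = train_classifier(train, config, classes=classes, seed=config.seed + f)
        conf = evaluate(handle, test)
        confusions.append(conf)
        accs.append(average_accuracy(conf))
        for i in range(len(classes)):
            aucs[f, i] = auc_ovr(conf, i)
        probs = handle.predict_proba([it.pixels for it in test])
        y = np.array([classes.index(it.label) for it in test])
        for i in range(len(classes)):
            rocs[f, i] = roc_auc_score((y == i).astype(int), probs[:, i])
    return ClassificationResult(
        classes=classes,
        confusions=confusions,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        std_accuracy=float(np.std(accs)),
        auc_per_class=aucs,
        roc_auc_per_class=rocs,
        config={
            "backend": config.backend, "epochs": config.epochs, "lr": config.lr,
            "batch_size": config.batch_size, "k": k, "mode": mode, "seed": seed,
            "backend_seed": config.seed,
        },
    )
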