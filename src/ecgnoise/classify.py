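"""Cross-validation folds and the image-classification training harness.

The protocol: five predefined cross-validation folds, each splitting the
cohort into 75% training, 5% validation and 20% test, with the five test
partitions disjoint and jointly covering every record.  The same fold
assignment is reused for every image dataset so that results across noise
conditions are comparable.  Training stops early when the validation loss
has exceeded its running minimum a fixed number of times consecutively
(default 5), the counter resetting whenever a new minimum is reached.

The classifier mirrors the transfer-learning shape of the study — a frozen,
non-learnable feature-extraction backbone and a replaced trainable
classification head — at desk scale: the backbone is block average-pooling
of the resized greyscale image to a coarse grid, and the head is a
multinomial logistic (softmax) layer trained by full-batch gradient
descent.  Only the head learns; the backbone never does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import CLASSES
from .transforms import TransformImage, resize_for_network


@dataclass
class FoldAssignment:
    """Predefined train/validation/test partition per fold, by position index."""

    n_folds: int
    #: fold index in {0..k-1} of the *test* partition each record belongs to
    test_fold: np.ndarray
    #: per fold: dict with "train", "val", "test" index arrays
    splits: list = field(default_factory=list)

    def indices(self, fold: int, part: str) -> np.ndarray:
        return self.splits[fold][part]


def _balanced_class_parts(counts_by_class: dict, k: int, order: list) -> dict:
    """Per-class fold sizes: near-equal within class, extras placed greedily
    on the currently smallest folds so the *total* fold sizes stay within 1."""
    totals = np.zeros(k, dtype=int)
    sizes = {}
    for label in order:
        n = counts_by_class[label]
        base, extra = divmod(n, k)
        cls_sizes = np.full(k, base, dtype=int)
        for _ in range(extra):
            # smallest running total; ties broken by fold index
            j = int(np.argmin(totals + cls_sizes))
            cls_sizes[j] += 1
        totals += cls_sizes
        sizes[label] = cls_sizes
    return sizes


def make_folds(
    record_ids: list,
    labels: list,
    k: int = 5,
    seed: int = 0,
    val_fraction: float = 0.05,
    stratify: bool = True,
) -> FoldAssignment:
    """Build k predefined stratified folds with 75/5/20 train/val/test splits.

    Test partitions are a disjoint cover of all records with sizes within
    one of each other (n=2678, k=5 gives sizes in {535, 536}).  Validation
    is carved stratified from the non-test portion at ``val_fraction`` of n.
    """
    record_ids = list(record_ids)
    labels = list(labels)
    n = len(record_ids)
    if len(labels) != n:
        raise ValueError("labels must align with record_ids")
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    rng = np.random.default_rng(seed)

    labels_arr = np.asarray(labels)
    if stratify:
        classes = [c for c in CLASSES if c in labels_arr] or sorted(set(labels))
    else:
        classes = ["_all"]
        labels_arr = np.full(n, "_all")

    # shuffle indices within class, then deal contiguous chunks to folds
    idx_by_class = {c: rng.permutation(np.flatnonzero(labels_arr == c)) for c in classes}
    sizes = _balanced_class_parts({c: len(idx_by_class[c]) for c in classes}, k, classes)

    test_fold = np.empty(n, dtype=int)
    for c in classes:
        pos = 0
        for f in range(k):
            chunk = idx_by_class[c][pos : pos + sizes[c][f]]
            test_fold[chunk] = f
            pos += sizes[c][f]

    n_val_total = int(round(val_fraction * n))
    splits = []
    for f in range(k):
        test_idx = np.sort(np.flatnonzero(test_fold == f))
        rest = np.flatnonzero(test_fold != f)
        # stratified validation carve-out from the non-test portion
        rest_labels = labels_arr[rest]
        val_parts, capacities = [], []
        remaining = n_val_total
        for j, c in enumerate(classes):
            c_idx = rest[rest_labels == c]
            c_idx = np.random.default_rng(seed * 1000003 + f * 101 + j).permutation(c_idx)
            quota = int(round(n_val_total * len(c_idx) / len(rest)))
            quota = max(0, min(quota, remaining, len(c_idx) - 1))
            val_parts.append(list(c_idx[:quota]))
            capacities.append(c_idx)
            remaining -= quota
        # distribute any rounding leftover to classes with spare capacity,
        # always keeping at least one training record per class
        j = 0
        while remaining > 0 and j < 10 * len(classes):
            part = val_parts[j % len(classes)]
            cap = capacities[j % len(classes)]
            if len(part) < len(cap) - 1:
                part.append(cap[len(part)])
                remaining -= 1
            j += 1
        flat = [i for part in val_parts for i in part]
        val_idx = np.sort(np.asarray(flat, int)) if flat else np.array([], int)
        train_idx = np.sort(np.setdiff1d(rest, val_idx))
        splits.append({"train": train_idx, "val": val_idx, "test": test_idx})

    return FoldAssignment(n_folds=k, test_fold=test_fold, splits=splits)


# ---------------------------------------------------------------------------
# early stopping

def early_stop_epoch(val_losses, patience: int = 5) -> int | None:
    """Index (0-based) of the epoch at which training stops, or None.

    Maintains the running minimum validation loss; a counter increments on
    every epoch whose loss is strictly larger than that minimum and resets
    to zero whenever a new (strictly smaller) minimum is achieved.  Training
    stops at the epoch where the counter reaches ``patience``.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    best = np.inf
    counter = 0
    for i, loss in enumerate(val_losses):
        if loss < best:
            best = loss
            counter = 0
        elif loss > best:
            counter += 1
            if counter >= patience:
                return i
        # loss == best: not larger, not a new minimum -> counter unchanged
    return None


# ---------------------------------------------------------------------------
# backbone + head classifier

def pooled_features(pixels: np.ndarray, pool_grid: int = 16) -> np.ndarray:
    """Frozen backbone: block average-pool a square image to pool_grid^2 features."""
    side = pixels.shape[0]
    step = side // pool_grid
    trim = step * pool_grid
    pooled = pixels[:trim, :trim].reshape(pool_grid, step, pool_grid, step).mean(axis=(1, 3))
    return pooled.ravel()


class PooledImageClassifier(BaseEstimator, ClassifierMixin):
    """Softmax head on frozen pooled-image features, with patience-based
    early stopping on a held-out validation set.

    Parameters
    ----------
    input_side : int
        Side the images are rescaled to before the backbone (224 or 227).
    pool_grid : int
        Backbone output grid (pool_grid**2 features).
    learning_rate, max_epochs, patience : training-loop controls; training
        halts at the earlier of ``max_epochs`` or the early-stopping rule.
    restore_best : bool
        If True (default) the head weights at the smallest validation loss
        are kept; otherwise the weights at the stopping epoch.
    seed : int
        Controls weight initialization; fitting is fully deterministic.
    """

    def __init__(
        self,
        input_side: int = 224,
        pool_grid: int = 16,
        learning_rate: float = 0.5,
        max_epochs: int = 50,
        patience: int = 5,
        l2: float = 1e-3,
        restore_best: bool = True,
        seed: int = 0,
    ):
        self.input_side = input_side
        self.pool_grid = pool_grid
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.l2 = l2
        self.restore_best = restore_best
        self.seed = seed

    # -- feature extraction ------------------------------------------------
    def _features(self, images) -> np.ndarray:
        rows = []
        for img in images:
            if isinstance(img, TransformImage):
                px = resize_for_network(img, self.input_side)
            else:
                px = np.asarray(img, float)
                if px.shape[0] != self.input_side:
                    px = resize_for_network(
                        TransformImage(np.clip(px, 0, 1), "attractor"), self.input_side
                    )
            rows.append(pooled_features(px, self.pool_grid))
        return np.asarray(rows)

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _loss(self, X, Y, W, b) -> float:
        p = self._softmax(X @ W + b)
        return float(-np.mean(np.sum(Y * np.log(p + 1e-12), axis=1)))

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Fit the head; ``X`` is a sequence of TransformImage or arrays.

        When no validation set is supplied, a deterministic 10% tail split
        of the training data is used for the stopping rule.
        """
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set must contain at least two classes")

        F = self._features(X)
        if X_val is not None:
            F_val = self._features(X_val)
            yv = np.asarray(y_val)
        else:
            n_val = max(1, len(F) // 10)
            F, F_val = F[:-n_val], F[-n_val:]
            y, yv = y[:-n_val], y[-n_val:]
            if len(np.unique(y)) < len(self.classes_):
                raise ValueError("internal validation split dropped a class; pass X_val")

        self.mean_ = F.mean(axis=0)
        self.scale_ = F.std(axis=0) + 1e-8
        Xs = (F - self.mean_) / self.scale_
        Xv = (F_val - self.mean_) / self.scale_

        cls_index = {c: i for i, c in enumerate(self.classes_)}
        Y = np.eye(len(self.classes_))[[cls_index[c] for c in y]]
        Yv = np.eye(len(self.classes_))[[cls_index[c] for c in yv]]

        rng = np.random.default_rng(self.seed)
        W = rng.normal(0, 0.01, (Xs.shape[1], len(self.classes_)))
        b = np.zeros(len(self.classes_))

        history = {"train_loss": [], "val_loss": []}
        best = np.inf
        best_Wb = (W.copy(), b.copy())
        counter = 0
        stopped = self.max_epochs - 1
        for epoch in range(self.max_epochs):
            p = self._softmax(Xs @ W + b)
            grad_z = (p - Y) / len(Xs)
            W -= self.learning_rate * (Xs.T @ grad_z + self.l2 * W)
            b -= self.learning_rate * grad_z.sum(axis=0)
            history["train_loss"].append(self._loss(Xs, Y, W, b))
            v = self._loss(Xv, Yv, W, b)
            history["val_loss"].append(v)
            if v < best:
                best, counter = v, 0
                best_Wb = (W.copy(), b.copy())
            elif v > best:
                counter += 1
                if counter >= self.patience:
                    stopped = epoch
                    break
        else:
            stopped = len(history["val_loss"]) - 1

        if self.restore_best:
            W, b = best_Wb
        self.coef_, self.intercept_ = W, b
        self.history_ = history
        self.stopped_epoch_ = stopped
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        F = self._features(X)
        if len(F) == 0:
            return np.zeros((0, len(self.classes_)))
        Xs = (F - self.mean_) / self.scale_
        return Xs @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        if len(z) == 0:
            return z
        return self._softmax(z)

    def predict(self, X) -> np.ndarray:
        z = self.decision_function(X)
        if len(z) == 0:
            return np.asarray([], dtype=self.classes_.dtype)
        return self.classes_[np.argmax(z, axis=1)]


@dataclass
class TrainConfig:
    """Configuration echoed into every trained-model artefact."""

    backbone: str = "pooled"
    input_side: int = 224
    pool_grid: int = 16
    learning_rate: float = 0.5
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0

    def build(self) -> PooledImageClassifier:
        if self.backbone != "pooled":
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.patience < 1:
            raise ValueError("early-stop patience must be >= 1")
        return PooledImageClassifier(
            input_side=self.input_side,
            pool_grid=self.pool_grid,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.seed,
        )


def train(images, labels, fold_split: dict, cfg: TrainConfig) -> PooledImageClassifier:
    """Train on a fold's train partition, early-stopping on its validation
    partition; ``images``/``labels`` are indexed by the split's positions."""
    tr, va = fold_split["train"], fold_split["val"]
    if len(tr) == 0 or len(va) == 0:
        raise ValueError("train and validation sets must be non-empty")
    labels = np.asarray(labels)
    present = set(labels[tr])
    missing = [c for c in set(labels) if c not in present]
    if missing:
        raise ValueError(f"class(es) {missing} absent from the training set")
    clf = cfg.build()
    clf.fit(
        [images[i] for i in tr], labels[tr],
        X_val=[images[i] for i in va], y_val=labels[va],
    )
    return clf
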