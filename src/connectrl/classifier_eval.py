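"""Biomarker evaluation with a feed-forward neural network.

Average-controllability values of the regions that separate the two groups
serve as features for a fully connected binary classifier: an input layer,
six ReLU hidden layers with dropout after each, and a sigmoid output
producing P(y = 1 | x). The network is trained with mini-batch Adam on the
binary cross-entropy and evaluated under stratified k-fold cross-validation
(per-fold confusion matrix, sensitivity/specificity, ROC and trapezoidal
AUC). Features are z-scored with training-fold statistics only, so no
information leaks from the held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .controllability import ControllabilityProfile
from .group_stats import ComparisonTable
from ._seeds import derive_seed

__all__ = [
    "FeatureMatrix",
    "MlpArchitecture",
    "FoldResult",
    "CVReport",
    "select_features",
    "stratified_folds",
    "train_mlp",
    "roc_auc",
    "cross_validate",
]


@dataclass(frozen=True)
class FeatureMatrix:
    x: np.ndarray               # n_subjects x n_features
    feature_names: list[str]
    y: np.ndarray               # binary labels, 0 = control-like, 1 = case-like

    def validate(self) -> None:
        if self.x.ndim != 2 or self.x.shape[0] != self.y.shape[0]:
            raise ValueError("feature matrix rows must match label count")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("feature matrix contains non-finite values")
        if self.x.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match column count")


@dataclass(frozen=True)
class MlpArchitecture:
    """Fully connected binary classifier: ReLU hidden stack, sigmoid output."""

    n_hidden_layers: int = 6
    hidden_width: int = 64
    dropout_rate: float = 0.25
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 32

    def validate(self) -> None:
        if self.n_hidden_layers < 1 or self.hidden_width < 1:
            raise ValueError("layer counts and widths must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")


@dataclass(frozen=True)
class FoldResult:
    fold_index: int
    tp: int
    tn: int
    fp: int
    fn: int
    roc_points: np.ndarray      # (n, 2) array of (fpr, tpr)
    auc: float

    @property
    def n_test(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_test


@dataclass(frozen=True)
class CVReport:
    fold_results: list[FoldResult]
    pooled_confusion: np.ndarray    # rows = true label (0, 1), cols = predicted
    overall_accuracy: float         # pooled over all held-out subjects
    fold_mean_accuracy: float
    class_rates: tuple[float, float]  # per-class correct-classification rates
    mean_auc: float
    sd_auc: float

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "fold_mean_accuracy": self.fold_mean_accuracy,
            "class_rate_0": self.class_rates[0],
            "class_rate_1": self.class_rates[1],
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "pooled_confusion": self.pooled_confusion.tolist(),
            "folds": [
                {
                    "fold": f.fold_index,
                    "tp": f.tp, "tn": f.tn, "fp": f.fp, "fn": f.fn,
                    "accuracy": f.accuracy,
                    "sensitivity": f.tpr,
                    "specificity": f.specificity,
                    "auc": f.auc,
                    "roc_points": np.asarray(f.roc_points).tolist(),
                }
                for f in self.fold_results
            ],
        }


def select_features(
    profiles: list[ControllabilityProfile],
    comparison_table: ComparisonTable | None = None,
    alpha: float = 0.05,
    regions: list[int] | None = None,
) -> FeatureMatrix:
    """Build the classifier feature matrix from significant regions.

    Columns are the regions whose t-test p falls below ``alpha`` (ordered by
    atlas ID), or an explicit 0-based ``regions`` override; rows follow
    cohort order.
    """
    if not profiles:
        raise ValueError("no profiles given")
    labels = profiles[0].region_labels
    if regions is None:
        if comparison_table is None:
            raise ValueError("need a comparison table or an explicit region list")
        selected = sorted(r.region_id - 1 for r in comparison_table.rows if r.p_t < alpha)
        if not selected:
            raise ValueError(
                f"no region significant at alpha={alpha}; pass an explicit regions list instead"
            )
    else:
        selected = sorted(regions)
        for r in selected:
            if not 0 <= r < len(labels):
                raise ValueError(f"region index {r} outside [0, {len(labels)})")
    x = np.array([[p.values[j] for j in selected] for p in profiles])
    y = np.array([p.group_label for p in profiles], dtype=int)
    fm = FeatureMatrix(x=x, feature_names=[labels[j] for j in selected], y=y)
    fm.validate()
    return fm


def stratified_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Assign each subject to one of k folds, stratified by class.

    Each class is shuffled and dealt round-robin onto the folds, with the
    dealing pointer continuing from one class to the next, so per-fold
    class counts and total fold sizes each differ by at most one from an
    even split. Deterministic for a fixed seed.
    """
    y = np.asarray(labels, dtype=int)
    n = y.size
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects ({n})")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    pointer = int(rng.integers(k))
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = (np.arange(idx.size) + pointer) % k
        pointer = (pointer + idx.size) % k
    return assignment


class _MlpScorer:
    """Trained network; maps feature rows to P(y = 1 | x)."""

    def __init__(self, weights, biases, mean, scale):
        self._weights = weights
        self._biases = biases
        self._mean = mean
        self._scale = scale

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        h = (np.atleast_2d(np.asarray(x, dtype=float)) - self._mean) / self._scale
        for w, b in zip(self._weights[:-1], self._biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        z = h @ self._weights[-1] + self._biases[-1]
        return 1.0 / (1.0 + np.exp(-z[:, 0]))


def train_mlp(
    x_train: np.ndarray,
    y_train: np.ndarray,
    arch: MlpArchitecture | None = None,
    seed: int = 0,
    standardize: bool = True,
) -> _MlpScorer:
    """Train the dropout MLP on one training split.

    Inverted dropout is active only during training; inference uses the
    full network. He-initialized weights, mini-batch Adam on binary
    cross-entropy. Deterministic for a fixed seed.
    """
    arch = arch or MlpArchitecture()
    arch.validate()
    x = np.asarray(x_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    if np.min(np.bincount(y.astype(int))) < 2:
        raise ValueError("need at least 2 subjects per class to train")

    if standardize:
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
    xs = (x - mean) / scale

    rng = np.random.default_rng(seed)
    sizes = [x.shape[1]] + [arch.hidden_width] * arch.n_hidden_layers + [1]
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(s) for s in sizes[1:]]

    # Adam state
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = arch.learning_rate
    keep = 1.0 - arch.dropout_rate
    step = 0
    n = xs.shape[0]

    for _ in range(arch.epochs):
        order = rng.permutation(n)
        for start in range(0, n, arch.batch_size):
            batch = order[start:start + arch.batch_size]
            xb, yb = xs[batch], y[batch]

            # forward with inverted dropout on hidden activations
            acts = [xb]
            masks = []
            h = xb
            for li in range(arch.n_hidden_layers):
                h = np.maximum(h @ weights[li] + biases[li], 0.0)
                if arch.dropout_rate > 0:
                    m = (rng.random(h.shape) < keep) / keep
                    h = h * m
                    masks.append(m)
                else:
                    masks.append(None)
                acts.append(h)
            z = h @ weights[-1] + biases[-1]
            p = 1.0 / (1.0 + np.exp(-z[:, 0]))

            # backward: d(BCE)/dz = (p - y) / batch
            delta = ((p - yb) / xb.shape[0])[:, None]
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            grads_w[-1] = acts[-1].T @ delta
            grads_b[-1] = delta.sum(axis=0)
            upstream = delta @ weights[-1].T
            for li in range(arch.n_hidden_layers - 1, -1, -1):
                if masks[li] is not None:
                    upstream = upstream * masks[li]
                upstream = upstream * (acts[li + 1] > 0)
                grads_w[li] = acts[li].T @ upstream
                grads_b[li] = upstream.sum(axis=0)
                if li > 0:
                    upstream = upstream @ weights[li].T

            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for li in range(len(weights)):
                mw[li] = beta1 * mw[li] + (1 - beta1) * grads_w[li]
                vw[li] = beta2 * vw[li] + (1 - beta2) * grads_w[li] ** 2
                weights[li] -= lr * (mw[li] / corr1) / (np.sqrt(vw[li] / corr2) + eps)
                mb[li] = beta1 * mb[li] + (1 - beta1) * grads_b[li]
                vb[li] = beta2 * vb[li] + (1 - beta2) * grads_b[li] ** 2
                biases[li] -= lr * (mb[li] / corr1) / (np.sqrt(vb[li] / corr2) + eps)

    return _MlpScorer(weights, biases, mean, scale)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points (threshold sweep over distinct scores) and trapezoidal AUC.

    The curve starts at (0, 0) and ends at (1, 1); the trapezoidal area
    equals the Mann-Whitney concordance probability.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, scores)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def cross_validate(
    features: FeatureMatrix,
    arch: MlpArchitecture | None = None,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVReport:
    """Stratified k-fold cross-validation of the MLP on the feature matrix.

    Each fold serves as the held-out test set once; the confusion matrix
    (true label x predicted label) is evaluated at the given probability
    threshold and pooled across folds.
    """
    features.validate()
    arch = arch or MlpArchitecture()
    y = features.y
    assignment = stratified_folds(y, k, seed=derive_seed(seed, 0xF01D))

    fold_results: list[FoldResult] = []
    pooled = np.zeros((2, 2), dtype=int)
    for fold in range(k):
        test = assignment == fold
        train = ~test
        scorer = train_mlp(
            features.x[train], y[train], arch=arch, seed=derive_seed(seed, 0x317, fold)
        )
        p = scorer.predict_proba(features.x[test])
        y_test = y[test]
        pred = (p >= threshold).astype(int)
        tp = int(np.sum((pred == 1) & (y_test == 1)))
        tn = int(np.sum((pred == 0) & (y_test == 0)))
        fp = int(np.sum((pred == 1) & (y_test == 0)))
        fn = int(np.sum((pred == 0) & (y_test == 1)))
        if np.unique(y_test).size == 2:
            points, auc = roc_auc(p, y_test)
        else:  # degenerate single-class fold (possible only for tiny cohorts)
            points, auc = np.array([[0.0, 0.0], [1.0, 1.0]]), float("nan")
        fold_results.append(FoldResult(fold, tp, tn, fp, fn, points, auc))
        pooled += np.array([[tn, fp], [fn, tp]])

    total = pooled.sum()
    overall = float((pooled[0, 0] + pooled[1, 1]) / total)
    rate0 = float(pooled[0, 0] / pooled[0].sum()) if pooled[0].sum() else float("nan")
    rate1 = float(pooled[1, 1] / pooled[1].sum()) if pooled[1].sum() else float("nan")
    aucs = np.array([f.auc for f in fold_results])
    return CVReport(
        fold_results=fold_results,
        pooled_confusion=pooled,
        overall_accuracy=overall,
        fold_mean_accuracy=float(np.mean([f.accuracy for f in fold_results])),
        class_rates=(rate0, rate1),
        mean_auc=float(np.nanmean(aucs)),
        sd_auc=float(np.nanstd(aucs)),
    )
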