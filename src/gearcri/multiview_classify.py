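"""Multi-view action classification: majority-vote SVM fusion vs. MI-SVM.

An *action instance* is one contiguous interval in which the child performs
a single action — crawling, sitting, standing or walking — observed
simultaneously by up to five cameras. Each instance is a *bag* of per-view
embedding vectors with one label. Two classifiers are implemented:

* **SVM-MV** — the instance label is transferred to every view, one linear
  SVM is trained on the unrolled views, and at test time the per-view
  predictions are fused by majority vote. Label transfer can mislabel
  views in which the action is occluded.
* **MI-SVM** — multiple-instance learning: for each class, training
  alternates between selecting a *witness* view per positive bag (the view
  scoring highest under the current model) and refitting a linear SVM on
  witnesses versus all views of negative bags. A bag's test score is the
  maximum over its views, so no voting is needed.

Evaluation follows a stratified-split protocol: several random splits with
a fixed fraction of each class in training, accuracy as the percentage of
correctly classified test instances averaged over splits, and a
row-normalized confusion matrix.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

ACTION_CLASSES: tuple[str, ...] = ("crawling", "sitting", "standing", "walking")


@dataclass
class MultiViewActionInstance:
    """Bag of per-view feature vectors for one action instance."""

    instance_id: str
    embeddings: dict[int, np.ndarray]  # view_id -> feature vector
    label: Optional[str] = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.embeddings:
            raise ValueError("an instance must have at least one view")
        dims = {len(v) for v in self.embeddings.values()}
        if len(dims) != 1:
            raise ValueError("all view embeddings must share one dimension")

    @property
    def views(self) -> list[int]:
        return sorted(self.embeddings)

    def matrix(self) -> np.ndarray:
        """Views stacked in view-id order, shape (n_views, dim)."""
        return np.stack([self.embeddings[v] for v in self.views])


@dataclass
class SplitPlan:
    """Stratified train/test splits over instance ids.

    Split ``i`` is shuffled with seed ``seed + i``, so the default plan's
    five splits use seeds 0-4. Per class, the training count is
    ``ceil(train_frac * class count)`` — the rounding that reproduces an
    80/20 protocol's totals exactly.
    """

    n_splits: int
    train_frac: float
    seed: int
    splits: list[tuple[list[str], list[str]]]


def make_splits(
    instances: Sequence[MultiViewActionInstance],
    n_splits: int = 5,
    train_frac: float = 0.8,
    seed: int = 0,
) -> SplitPlan:
    """Random stratified splits: per class, ``ceil(train_frac * n)`` in training."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    by_class: dict[str, list[str]] = {}
    for inst in instances:
        if inst.label is None:
            raise ValueError(f"instance {inst.instance_id} is unlabeled")
        by_class.setdefault(inst.label, []).append(inst.instance_id)
    for label, ids in by_class.items():
        if len(ids) < 2:
            raise ValueError(
                f"class {label!r} has {len(ids)} instance(s); need >= 2 to stratify"
            )
    splits = []
    for k in range(n_splits):
        rng = np.random.default_rng(seed + k)
        train: list[str] = []
        test: list[str] = []
        for label in sorted(by_class):
            ids = sorted(by_class[label])
            perm = rng.permutation(len(ids))
            n_train = math.ceil(train_frac * len(ids))
            train.extend(ids[i] for i in perm[:n_train])
            test.extend(ids[i] for i in perm[n_train:])
        splits.append((train, test))
    return SplitPlan(n_splits=n_splits, train_frac=train_frac, seed=seed, splits=splits)


@dataclass
class LinearModel:
    """One-vs-rest linear model: per-class weight vector and bias."""

    classes: tuple[str, ...]
    weights: np.ndarray  # (n_classes, dim)
    biases: np.ndarray  # (n_classes,)
    approach: str  # "SVM-MV" | "MI-SVM"
    C: float
    seed: int
    n_iterations: int = 1
    converged: bool = True
    objective_history: dict[str, list[float]] = field(default_factory=dict)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores for feature rows, shape (n_rows, n_classes)."""
        return X @ self.weights.T + self.biases


def _ordered_classes(labels: set[str]) -> tuple[str, ...]:
    known = [c for c in ACTION_CLASSES if c in labels]
    extra = sorted(labels - set(ACTION_CLASSES))
    return tuple(known + extra)


def _fit_binary(X: np.ndarray, y: np.ndarray, C: float, seed: int) -> tuple[np.ndarray, float]:
    clf = LinearSVC(
        C=C,
        loss="squared_hinge",
        dual=False,
        tol=1e-7,
        random_state=seed,
        max_iter=10_000,
    )
    clf.fit(X, y)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    if clf.classes_[1] != 1:  # ensure the positive class drives the sign
        w, b = -w, -b
    return w, b


def _check_classes(
    bags: Sequence[MultiViewActionInstance], classes: Optional[Sequence[str]]
) -> tuple[str, ...]:
    seen = {b.label for b in bags}
    if None in seen:
        raise ValueError("all training bags must be labeled")
    if classes is None:
        return _ordered_classes(seen)
    missing = [c for c in classes if c not in seen]
    if missing:
        raise ValueError(f"class(es) {missing} absent from the training set")
    return tuple(classes)


def train_svm_mv(
    train_bags: Sequence[MultiViewActionInstance],
    C: float = 1.0,
    seed: int = 0,
    classes: Optional[Sequence[str]] = None,
) -> LinearModel:
    """Train the majority-vote approach: label transfer, then one linear SVM.

    Each bag's label is transferred to every one of its views; the
    one-vs-rest SVM is fitted on the unrolled per-view vectors.
    """
    cls = _check_classes(train_bags, classes)
    X, y = unroll_views(train_bags)
    W = np.empty((len(cls), X.shape[1]))
    b = np.empty(len(cls))
    for i, c in enumerate(cls):
        W[i], b[i] = _fit_binary(X, np.where(y == c, 1, -1), C, seed)
    return LinearModel(cls, W, b, approach="SVM-MV", C=C, seed=seed)


def unroll_views(
    bags: Sequence[MultiViewActionInstance],
) -> tuple[np.ndarray, np.ndarray]:
    """Label-transfer expansion: one row per view, carrying its bag's label."""
    X = np.concatenate([bag.matrix() for bag in bags])
    y = np.concatenate(
        [np.full(len(bag.views), bag.label, dtype=object) for bag in bags]
    )
    return X, y


def predict_mv(model: LinearModel, bag: MultiViewActionInstance) -> str:
    """Majority vote over the bag's per-view SVM predictions.

    Vote ties are broken by the larger sum of per-view decision scores
    among the tied classes, then by the fixed class order.
    """
    if model.approach != "SVM-MV":
        raise ValueError("model was not trained with the SVM-MV approach")
    scores = model.decision_scores(bag.matrix())  # (n_views, n_classes)
    view_preds = scores.argmax(axis=1)
    votes = Counter(view_preds)
    top = max(votes.values())
    tied = [c for c, n in votes.items() if n == top]
    if len(tied) > 1:
        sums = scores[:, tied].sum(axis=0)
        tied = [tied[int(np.argmax(sums))]]
    return model.classes[tied[0]]


def _squared_hinge_objective(
    w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, C: float
) -> float:
    margins = y * (X @ w + b)
    return 0.5 * float(w @ w) + C * float((np.clip(1 - margins, 0, None) ** 2).sum())


def train_mi_svm(
    train_bags: Sequence[MultiViewActionInstance],
    C: float = 1.0,
    seed: int = 0,
    max_alternations: int = 20,
    classes: Optional[Sequence[str]] = None,
) -> LinearModel:
    """Train the multiple-instance approach by witness alternation.

    Per class, iteration 0 starts from label transfer (every view of each
    positive bag counts as positive). Thereafter the algorithm alternates:
    pick one witness view per positive bag (highest current decision
    score), refit the binary SVM on witnesses versus all views of negative
    bags, and stop when the witness assignment is stable or
    ``max_alternations`` is reached.
    """
    cls = _check_classes(train_bags, classes)
    dim = len(next(iter(train_bags[0].embeddings.values())))
    W = np.empty((len(cls), dim))
    b = np.empty(len(cls))
    converged_all = True
    n_iter_max = 0
    history: dict[str, list[float]] = {}
    for i, c in enumerate(cls):
        pos = [bag for bag in train_bags if bag.label == c]
        neg = [bag for bag in train_bags if bag.label != c]
        X_neg = np.concatenate([bag.matrix() for bag in neg]) if neg else np.empty((0, dim))
        pos_mats = [bag.matrix() for bag in pos]
        # iteration 0: label-transfer initialization
        X0 = np.concatenate(pos_mats + [X_neg])
        y0 = np.concatenate([np.ones(sum(len(m) for m in pos_mats)), -np.ones(len(X_neg))])
        w_c, b_c = _fit_binary(X0, y0, C, seed)
        witnesses: Optional[list[int]] = None
        converged = False
        objs: list[float] = []
        n_iter = 0
        for n_iter in range(1, max_alternations + 1):
            new_wit = [int(np.argmax(m @ w_c + b_c)) for m in pos_mats]
            X_wit = np.stack([m[j] for m, j in zip(pos_mats, new_wit)])
            Xc = np.concatenate([X_wit, X_neg])
            yc = np.concatenate([np.ones(len(X_wit)), -np.ones(len(X_neg))])
            if new_wit == witnesses:
                converged = True
                break
            witnesses = new_wit
            w_c, b_c = _fit_binary(Xc, yc, C, seed)
            objs.append(_squared_hinge_objective(w_c, b_c, Xc, yc, C))
        if not converged:
            logger.warning(
                "MI-SVM for class %r did not converge in %d alternations", c, max_alternations
            )
        converged_all &= converged
        n_iter_max = max(n_iter_max, n_iter)
        history[c] = objs
        W[i], b[i] = w_c, b_c
    return LinearModel(
        cls,
        W,
        b,
        approach="MI-SVM",
        C=C,
        seed=seed,
        n_iterations=n_iter_max,
        converged=converged_all,
        objective_history=history,
    )


def bag_scores_mi(model: LinearModel, bag: MultiViewActionInstance) -> np.ndarray:
    """MI-SVM bag score per class: the maximum decision score over views."""
    return model.decision_scores(bag.matrix()).max(axis=0)


def predict_mi(model: LinearModel, bag: MultiViewActionInstance) -> str:
    """Label of the class with the highest max-over-views score (no voting).

    Exact score ties break toward the earlier class in the fixed order.
    """
    if model.approach != "MI-SVM":
        raise ValueError("model was not trained with the MI-SVM approach")
    return model.classes[int(np.argmax(bag_scores_mi(model, bag)))]


def predict(model: LinearModel, bag: MultiViewActionInstance) -> str:
    return predict_mv(model, bag) if model.approach == "SVM-MV" else predict_mi(model, bag)


@dataclass
class EvalResult:
    """Split-protocol evaluation summary.

    Accuracies are percentages of correctly classified test instances;
    confusion matrices have ground-truth rows normalized to percent.
    """

    approach: str
    classes: tuple[str, ...]
    split_accuracies: list[float]
    confusion_matrices: list[np.ndarray]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.split_accuracies))

    @property
    def mean_confusion(self) -> np.ndarray:
        return np.mean(self.confusion_matrices, axis=0)

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "classes": list(self.classes),
            "split_accuracies": self.split_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "confusion_matrices": [m.tolist() for m in self.confusion_matrices],
            "mean_confusion": self.mean_confusion.tolist(),
        }


def plot_confusion(result: "EvalResult", path) -> None:
    """Save the split-averaged row-normalized confusion matrix as a heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conf = result.mean_confusion
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(conf, cmap="Blues", vmin=0, vmax=100)
    ax.set_xticks(range(len(result.classes)), result.classes, rotation=45, ha="right")
    ax.set_yticks(range(len(result.classes)), result.classes)
    ax.set_xlabel("predicted")
    ax.set_ylabel("ground truth")
    ax.set_title(f"{result.approach} (mean acc {result.mean_accuracy:.1f}%)")
    for i in range(len(result.classes)):
        for j in range(len(result.classes)):
            ax.text(
                j, i, f"{conf[i, j]:.0f}", ha="center", va="center",
                color="white" if conf[i, j] > 50 else "black", fontsize=8,
            )
    fig.colorbar(im, ax=ax, label="% of class")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def evaluate(
    approach: str,
    instances: Sequence[MultiViewActionInstance],
    split_plan: SplitPlan,
    C: float = 1.0,
    seed: int = 0,
    max_alternations: int = 20,
) -> EvalResult:
    """Run the full split protocol for one approach.

    Trains on each split's training bags, predicts its test bags, and
    reports per-split accuracy, the mean over splits, and row-normalized
    confusion matrices.
    """
    if approach not in ("SVM-MV", "MI-SVM"):
        raise ValueError("approach must be 'SVM-MV' or 'MI-SVM'")
    by_id = {inst.instance_id: inst for inst in instances}
    classes = _ordered_classes({inst.label for inst in instances})
    cls_idx = {c: i for i, c in enumerate(classes)}
    accs: list[float] = []
    confusions: list[np.ndarray] = []
    for train_ids, test_ids in split_plan.splits:
        train_bags = [by_id[i] for i in train_ids]
        test_bags = [by_id[i] for i in test_ids]
        if approach == "SVM-MV":
            model = train_svm_mv(train_bags, C=C, seed=seed, classes=classes)
        else:
            model = train_mi_svm(
                train_bags, C=C, seed=seed, max_alternations=max_alternations, classes=classes
            )
        conf = np.zeros((len(classes), len(classes)))
        n_correct = 0
        for bag in test_bags:
            pred = predict(model, bag)
            conf[cls_idx[bag.label], cls_idx[pred]] += 1
            n_correct += pred == bag.label
        accs.append(100.0 * n_correct / len(test_bags))
        row_tot = conf.sum(axis=1, keepdims=True)
        conf = np.divide(100.0 * conf, row_tot, out=np.zeros_like(conf), where=row_tot > 0)
        confusions.append(conf)
    return EvalResult(approach, classes, accs, confusions)
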