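"""Multi-class soft-margin RBF SVM with max-wins voting and 10-fold CV.

The classifier is the statistical core of the pipeline: one soft-margin
binary SVM per unordered class pair (one-vs-one), Gaussian RBF kernel
k(x_i, x_j) = exp(-gamma ||x_i - x_j||^2), defaults C = 100 and
gamma = 1/32 (one over the number of retained features).  Prediction uses
max-wins voting over the pairwise decisions; k-fold cross-validation
records per-run training/test misclassification counts and the pooled
confusion matrix, with

    accuracy = 1 - (total misclassified) / (total samples).

The binary quadratic-programming solver is scikit-learn's SVC operating on
this module's own precomputed Gram matrices; pairing, voting, tie-breaking,
fold accounting and all metrics are implemented here.

The API follows the model/results convention: :class:`FractalSVM` is built
from data, ``fit()`` returns a :class:`FractalSVMResults`, and
``cross_validate()`` returns a :class:`CVReport`; both results objects have
a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "SVMParams",
    "FractalSVM",
    "FractalSVMResults",
    "CVReport",
    "ClassMetrics",
    "StabilityReport",
    "rbf_kernel",
    "rbf_gram",
    "kfold_cv",
    "class_metrics",
    "repeat_cv_stability",
]


@dataclass(frozen=True)
class SVMParams:
    """Soft-margin penalty C and RBF kernel width gamma."""

    C: float = 100.0
    gamma: float = 1.0 / 32.0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


def rbf_kernel(x, y, gamma: float) -> float:
    """Gaussian RBF kernel exp(-gamma ||x - y||^2); in (0, 1], symmetric."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.exp(-gamma * np.sum((x - y) ** 2)))


def rbf_gram(X, Y=None, gamma: float = 1.0 / 32.0) -> np.ndarray:
    """Gram matrix K[i, j] = exp(-gamma ||X_i - Y_j||^2)."""
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("dimension mismatch between X and Y")
    sq = (
        (X ** 2).sum(axis=1)[:, None]
        + (Y ** 2).sum(axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class FractalSVM:
    """One-vs-one RBF SVM over a feature matrix and class labels.

    Parameters
    ----------
    X : (n, p) array
        Feature matrix (for fingerprints: the 32 retained fractal features).
    y : (n,) array
        Class labels (disease level D or flow rate Q).
    params : SVMParams
        C and gamma; defaults C = 100, gamma = 1/32.
    scale : bool
        Standardise features before training (off by default: fractal
        dimensions already live on a common [0, 2] scale).
    """

    def __init__(self, X, y, params: SVMParams | None = None, scale: bool = False):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (n, p) with labels aligned")
        self.params = params or SVMParams()
        self.scale = scale
        self._mu = None
        self._sd = None
        self.classes_ = np.unique(self.y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        label: str = "D",
        feature_prefix: str = "f",
        params: SVMParams | None = None,
        scale: bool = False,
    ) -> "FractalSVM":
        """Build from a feature table (columns f01.. plus a label column)."""
        feats = [c for c in table.columns if c.startswith(feature_prefix) and c[1:].isdigit()]
        if not feats:
            raise ValueError(f"no feature columns with prefix {feature_prefix!r}")
        if label not in table.columns:
            raise ValueError(f"label column {label!r} not in table")
        return cls(table[feats].to_numpy(), table[label].to_numpy(), params, scale)

    def fit(self) -> "FractalSVMResults":
        X = self.X
        if self.scale:
            self._mu = X.mean(axis=0)
            self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
            X = (X - self._mu) / self._sd
        else:
            self._mu = None
            self._sd = None
        machines = {}
        for a, b in combinations(self.classes_, 2):
            idx = np.where((self.y == a) | (self.y == b))[0]
            Xp = X[idx]
            yp = (self.y[idx] == b).astype(int)  # 1 <-> class b
            gram = rbf_gram(Xp, gamma=self.params.gamma)
            svc = SVC(C=self.params.C, kernel="precomputed")
            svc.fit(gram, yp)
            machines[(a, b)] = (svc, Xp)
        res = FractalSVMResults(model=self, machines=machines)
        res.training_errors = int((res.predict(self.X) != self.y).sum())
        return res


@dataclass
class FractalSVMResults:
    """Fitted pairwise machines plus the max-wins voting predictor."""

    model: FractalSVM
    machines: dict
    training_errors: int = 0

    def decision_values(self, X) -> dict:
        """Per class-pair signed decision values for each sample in X."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError("feature dimension mismatch with training data")
        if self.model._mu is not None:
            X = (X - self.model._mu) / self.model._sd
        out = {}
        for pair, (svc, Xp) in self.machines.items():
            gram = rbf_gram(X, Xp, gamma=self.model.params.gamma)
            out[pair] = svc.decision_function(gram)
        return out

    def predict(self, X):
        """Max-wins voting; ties broken by the largest summed absolute
        decision values among tied classes, then by the lowest class index."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        decisions = self.decision_values(X)
        n = len(X[None, :] if single else X)
        classes = self.model.classes_
        cindex = {c: i for i, c in enumerate(classes)}
        votes = np.zeros((n, len(classes)))
        strength = np.zeros((n, len(classes)))
        for (a, b), d in decisions.items():
            win_b = d > 0
            votes[:, cindex[b]] += win_b
            votes[:, cindex[a]] += ~win_b
            strength[np.where(win_b)[0], cindex[b]] += np.abs(d[win_b])
            strength[np.where(~win_b)[0], cindex[a]] += np.abs(d[~win_b])
        labels = np.empty(n, dtype=classes.dtype)
        for i in range(n):
            top = votes[i].max()
            tied = np.where(votes[i] == top)[0]
            if len(tied) > 1:
                best = strength[i, tied].max()
                tied = tied[strength[i, tied] == best]  # then lowest index
            labels[i] = classes[tied[0]]
        return labels[0] if single else labels

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "One-vs-one RBF SVM",
            f"  classes:          {list(self.model.classes_)}",
            f"  samples x feats:  {self.model.X.shape[0]} x {self.model.X.shape[1]}",
            f"  C, gamma:         {p.C:g}, {p.gamma:g}",
            f"  pairwise SVMs:    {len(self.machines)}",
            f"  training errors:  {self.training_errors}",
        ]
        for pair, (svc, _) in sorted(self.machines.items(), key=lambda kv: str(kv[0])):
            lines.append(f"    {pair}: {int(svc.n_support_.sum())} support vectors")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """k-fold cross-validation accounting.

    per_run_train_errors / per_run_test_errors follow the published table
    layout (one count per run); accuracy = 1 - total misclassified / n.
    """

    k: int
    seed: int
    classes: np.ndarray
    per_run_train_errors: list[int]
    per_run_test_errors: list[int]
    confusion_matrix: np.ndarray
    fold_assignment: np.ndarray
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    sample_ids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.true_labels)

    @property
    def total_misclassified(self) -> int:
        return int(sum(self.per_run_test_errors))

    @property
    def accuracy(self) -> float:
        return 1.0 - self.total_misclassified / self.n

    @property
    def misclassified_ids(self) -> list:
        bad = self.predicted_labels != self.true_labels
        return list(self.sample_ids[bad])

    def summary(self) -> str:
        runs = " ".join(f"{i + 1:>3d}" for i in range(self.k))
        tr = " ".join(f"{e:>3d}" for e in self.per_run_train_errors)
        te = " ".join(f"{e:>3d}" for e in self.per_run_test_errors)
        train_acc = 1.0 - sum(self.per_run_train_errors) / ((self.k - 1) * self.n)
        lines = [
            f"{self.k}-fold cross-validation (n = {self.n}, seed = {self.seed})",
            f"  Run      {runs}  Total  Accuracy",
            f"  Training {tr}  {sum(self.per_run_train_errors):>5d}  {train_acc:.1%}",
            f"  Testing  {te}  {self.total_misclassified:>5d}  {self.accuracy:.1%}",
            "  Confusion matrix (rows true, cols predicted):",
        ]
        hdr = "        " + " ".join(f"{c!s:>5}" for c in self.classes)
        lines.append(hdr)
        for i, c in enumerate(self.classes):
            lines.append(
                f"  {c!s:>5} " + " ".join(f"{v:>5d}" for v in self.confusion_matrix[i])
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "classes": [c.item() if hasattr(c, "item") else c for c in self.classes],
            "per_run_train_errors": list(map(int, self.per_run_train_errors)),
            "per_run_test_errors": list(map(int, self.per_run_test_errors)),
            "total_misclassified": self.total_misclassified,
            "accuracy": self.accuracy,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "misclassified_ids": [str(s) for s in self.misclassified_ids],
        }


def _fold_split(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Unstratified uniform random partition into k near-equal folds."""
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = fold
    return assignment


def _stratified_split(y, k: int, rng: np.random.Generator) -> np.ndarray:
    assignment = np.empty(len(y), dtype=int)
    offset = 0
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        perm = rng.permutation(idx)
        folds = (np.arange(len(perm)) + offset) % k
        assignment[perm] = folds
        offset += len(perm)
    return assignment


def kfold_cv(
    X,
    y,
    k: int = 10,
    seed: int = 0,
    params: SVMParams | None = None,
    sample_ids=None,
    stratified: bool = False,
    scale: bool = False,
) -> CVReport:
    """Seeded k-fold cross-validation with per-run error accounting.

    The dataset is randomly partitioned into k near-equal subsets
    (unstratified by default); each run trains on k-1 folds and tests on
    the remaining one, so every sample is tested exactly once.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of samples {n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = np.asarray(sample_ids) if sample_ids is not None else np.array(
        [f"S{i + 1}" for i in range(n)]
    )
    rng = np.random.default_rng(seed)
    folds = _stratified_split(y, k, rng) if stratified else _fold_split(n, k, rng)

    classes = np.unique(y)
    cindex = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    predicted = np.empty_like(y)
    train_errs, test_errs = [], []
    for fold in range(k):
        test = folds == fold
        train = ~test
        res = FractalSVM(X[train], y[train], params=params, scale=scale).fit()
        train_errs.append(res.training_errors)
        pred = res.predict(X[test])
        predicted[test] = pred
        test_errs.append(int((pred != y[test]).sum()))
        for t, p in zip(y[test], pred):
            confusion[cindex[t], cindex[p]] += 1
    return CVReport(
        k=k,
        seed=seed,
        classes=classes,
        per_run_train_errors=train_errs,
        per_run_test_errors=test_errs,
        confusion_matrix=confusion,
        fold_assignment=folds,
        true_labels=y,
        predicted_labels=predicted,
        sample_ids=ids,
    )


# convenience binding on the model class
def _cross_validate(self, k: int = 10, seed: int = 0, sample_ids=None,
                    stratified: bool = False) -> CVReport:
    return kfold_cv(
        self.X, self.y, k=k, seed=seed, params=self.params,
        sample_ids=sample_ids, stratified=stratified, scale=self.scale,
    )


FractalSVM.cross_validate = _cross_validate


# ---------------------------------------------------------------------------
# metrics and stability
# ---------------------------------------------------------------------------


@dataclass
class ClassMetrics:
    """Sensitivity/specificity for a positive-class grouping plus per-class
    sensitivities of the full multi-class confusion matrix."""

    sensitivity: float
    specificity: float
    false_negatives: int
    false_positives: int
    per_class_sensitivity: dict


def class_metrics(report: CVReport, positive_classes) -> ClassMetrics:
    """Collapse the confusion matrix by a positive-class grouping.

    sensitivity = TP / (TP + FN), specificity = TN / (TN + FP); the
    grouping must be a non-empty proper subset of the classes.
    """
    pos = list(positive_classes)
    classes = list(report.classes)
    if not pos:
        raise ValueError("positive grouping must be non-empty")
    if not set(pos) < set(classes):
        raise ValueError("positive grouping must be a proper subset of the classes")
    is_pos = np.array([c in pos for c in classes])
    cm = report.confusion_matrix
    tp = int(cm[np.ix_(is_pos, is_pos)].sum())
    fn = int(cm[np.ix_(is_pos, ~is_pos)].sum())
    fp = int(cm[np.ix_(~is_pos, is_pos)].sum())
    tn = int(cm[np.ix_(~is_pos, ~is_pos)].sum())
    per_class = {
        c: (cm[i, i] / cm[i].sum() if cm[i].sum() else float("nan"))
        for i, c in enumerate(classes)
    }
    return ClassMetrics(
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        false_negatives=fn,
        false_positives=fp,
        per_class_sensitivity=per_class,
    )


@dataclass
class StabilityReport:
    """Repeated-CV robustness: per-seed accuracy and misclassified-id sets."""

    seeds: list
    reports: list
    accuracies: list
    misclassified_sets: list
    intersection: set

    def summary(self) -> str:
        lines = ["Repeated cross-validation stability"]
        for s, a, m in zip(self.seeds, self.accuracies, self.misclassified_sets):
            lines.append(f"  seed {s}: accuracy {a:.1%}, misclassified {sorted(m)}")
        lines.append(f"  persistent misclassifications: {sorted(self.intersection)}")
        return "\n".join(lines)


def repeat_cv_stability(
    X,
    y,
    k: int = 10,
    seeds=(0, 1),
    params: SVMParams | None = None,
    sample_ids=None,
    stratified: bool = False,
) -> StabilityReport:
    """Re-run k-fold CV under several fold randomisations and intersect the
    misclassified-sample sets across repeats."""
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    reports = [
        kfold_cv(X, y, k=k, seed=s, params=params, sample_ids=sample_ids,
                 stratified=stratified)
        for s in seeds
    ]
    sets = [set(r.misclassified_ids) for r in reports]
    inter = set.intersection(*sets) if sets else set()
    return StabilityReport(
        seeds=seeds,
        reports=reports,
        accuracies=[r.accuracy for r in reports],
        misclassified_sets=sets,
        intersection=inter,
    )
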