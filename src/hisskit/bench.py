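"""Benchmark classifiers, evaluation metrics and data-sizing analyses.

Baselines are behavioural contracts over standard scikit-learn
estimators: a linear-kernel SVM, a bagged decision-tree ensemble with a
cross-entropy split criterion (6..20 estimators, step 2), and a
one-hidden-layer softmax network with a regularized objective.  The
module also provides k-fold cross-validation, learning curves over a
fixed held-out test set, one-way ANOVA across classifiers, and a
quadratic response surface used to predict how many patients and
experts a target accuracy requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

BASELINE_KINDS = ("svm_linear", "ebdt", "ann")

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "svm_linear": [{"C": c} for c in (0.1, 1.0, 10.0, 100.0)],
    "ebdt": [{"n_estimators": n} for n in range(6, 21, 2)],
    "ann": [{"hidden_layer_sizes": (h,)} for h in (5, 15, 25)],
}


class UnreachableTargetError(ValueError):
    """Raised when no (patients, experts) pair reaches the target accuracy."""


def _make_estimator(kind: str, params: dict, seed: int):
    if kind == "svm_linear":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", random_state=seed, **params))
    if kind == "ebdt":
        base = DecisionTreeClassifier(criterion="log_loss", random_state=seed)
        return BaggingClassifier(estimator=base, random_state=seed, **params)
    if kind == "ann":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                activation="tanh",
                solver="lbfgs",
                alpha=1e-2,
                max_iter=3000,
                random_state=seed,
                **params,
            ),
        )
    raise ValueError(f"unknown baseline kind {kind!r}; valid kinds: {BASELINE_KINDS}")


def estimator_factory(kind: str, params: dict | None = None,
                      seed: int = 0) -> Callable[[], object]:
    """A zero-argument factory producing identically configured estimators."""
    params = params or {}
    return lambda: _make_estimator(kind, params, seed)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (c, c), rows true, columns predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    per_class_tpr: dict[int, float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def confusion_and_accuracy(
    y_true: Sequence[int], y_pred: Sequence[int], c: int = 5
) -> tuple[ConfusionMatrix, float, dict[int, float]]:
    """Confusion matrix, trace accuracy and per-class sensitivity.

    Classes absent from ``y_true`` are omitted from the TPR mapping
    rather than reported as zero.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape[0]} true vs {yp.shape[0]} predicted")
    if yt.size == 0:
        raise ValueError("cannot evaluate empty prediction vectors")
    if np.any((yt < 0) | (yt >= c)) or np.any((yp < 0) | (yp >= c)):
        raise ValueError(f"labels must lie in 0..{c - 1}")
    counts = np.zeros((c, c), dtype=int)
    np.add.at(counts, (yt, yp), 1)
    cm = ConfusionMatrix(counts)
    tpr = {}
    for k in range(c):
        row = counts[k].sum()
        if row > 0:
            tpr[k] = counts[k, k] / row
    return cm, cm.accuracy, tpr


def kfold_cv(
    factory: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> CVResult:
    """Stratified-where-possible k-fold cross-validation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"cannot split {n} instances into {k} folds")
    rng = rng if rng is not None else np.random.default_rng()
    split_seed = int(rng.integers(2**31 - 1))
    counts = np.bincount(y)
    present = counts[counts > 0]
    min_count = int(present.min()) if present.size else 0
    if min_count >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=split_seed)
    else:
        warnings.warn(
            "class counts too small for stratified folds; using plain k-fold",
            stacklevel=2,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=split_seed)
    accs = []
    y_true_all: list[int] = []
    y_pred_all: list[int] = []
    for train_idx, test_idx in splitter.split(X, y):
        est = factory()
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
        y_true_all.extend(y[test_idx])
        y_pred_all.extend(int(p) for p in pred)
    c = int(max(max(y_true_all), max(y_pred_all))) + 1
    _, _, tpr = confusion_and_accuracy(y_true_all, y_pred_all, c=max(c, 5))
    return CVResult(fold_accuracies=np.asarray(accs), per_class_tpr=tpr)


def train_baseline(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    hyper_grid: list[dict] | None = None,
    rng: np.random.Generator | None = None,
    cv_folds: int = 5,
):
    """Fit the best hyper-grid member (selected by CV accuracy) on all data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind {kind!r}; valid kinds: {BASELINE_KINDS}")
    rng = rng if rng is not None else np.random.default_rng()
    est_seed = int(rng.integers(2**31 - 1))
    grid = hyper_grid if hyper_grid is not None else DEFAULT_GRIDS[kind]
    best_params, best_score = None, -np.inf
    for params in grid:
        cv_rng = np.random.default_rng(est_seed)  # same folds for every grid member
        result = kfold_cv(estimator_factory(kind, params, est_seed), X, y,
                          k=cv_folds, rng=cv_rng)
        if result.mean > best_score:
            best_params, best_score = params, result.mean
    est = _make_estimator(kind, best_params, est_seed)
    est.fit(X, y)
    return est


@dataclass
class LearningCurvePoint:
    train_size: int
    train_mean: float
    train_sd: float
    test_mean: float
    test_sd: float
    test_accuracies: np.ndarray = field(default_factory=lambda: np.empty(0))


def learning_curve(
    factory: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    train_sizes: Sequence[int],
    repeats: int = 20,
    test_size: int = 20,
    rng: np.random.Generator | None = None,
    stratified: bool = False,
) -> list[LearningCurvePoint]:
    """Accuracy vs. training-set size over a fixed held-out test set.

    For each size, ``repeats`` random training subsets are drawn from the
    non-test instances; ``stratified=True`` samples the training subset
    with class proportions preserved where counts permit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.shape[0]
    sizes = sorted(int(s) for s in train_sizes)
    if not sizes:
        raise ValueError("train_sizes must be non-empty")
    if sizes[0] < 1 or max(sizes) + test_size > n:
        raise ValueError(
            f"infeasible sizes: max train {max(sizes)} + test {test_size} exceeds n={n}"
        )
    rng = rng if rng is not None else np.random.default_rng()
    perm = rng.permutation(n)
    test_idx = perm[:test_size]
    pool = perm[test_size:]
    points = []
    for size in sizes:
        train_accs, test_accs = [], []
        for _ in range(repeats):
            if stratified:
                idx = _stratified_subset(y, pool, size, rng)
            else:
                idx = rng.choice(pool, size=size, replace=False)
            if np.unique(y[idx]).size < 2:  # degenerate subset; redraw once
                idx = rng.choice(pool, size=size, replace=False)
            est = factory()
            est.fit(X[idx], y[idx])
            train_accs.append(float(np.mean(est.predict(X[idx]) == y[idx])))
            test_accs.append(float(np.mean(est.predict(X[test_idx]) == y[test_idx])))
        points.append(
            LearningCurvePoint(
                train_size=size,
                train_mean=float(np.mean(train_accs)),
                train_sd=float(np.std(train_accs, ddof=1)) if repeats > 1 else 0.0,
                test_mean=float(np.mean(test_accs)),
                test_sd=float(np.std(test_accs, ddof=1)) if repeats > 1 else 0.0,
                test_accuracies=np.asarray(test_accs),
            )
        )
    return points


def _stratified_subset(y: np.ndarray, pool: np.ndarray, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Class-proportional subset of ``pool`` (80:20-style sorted sampling)."""
    chosen: list[int] = []
    classes = np.unique(y[pool])
    fractions = {k: np.sum(y[pool] == k) / pool.size for k in classes}
    for k in classes:
        members = pool[y[pool] == k]
        take = min(len(members), max(1, int(round(fractions[k] * size))))
        chosen.extend(rng.choice(members, size=take, replace=False))
    chosen = np.asarray(chosen)
    if chosen.size > size:
        chosen = rng.choice(chosen, size=size, replace=False)
    elif chosen.size < size:
        rest = np.setdiff1d(pool, chosen)
        extra = rng.choice(rest, size=size - chosen.size, replace=False)
        chosen = np.concatenate([chosen, extra])
    return chosen


def compare_classifiers_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across classifiers' fold accuracies."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA requires >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    if ss_between == 0.0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


@dataclass
class SizingModel:
    """Quadratic response surface: accuracy ~ f(n_patients, n_experts)."""

    coefficients: np.ndarray  # [1, p, e, p^2, e^2, p*e]
    r_squared: float
    ss_total: float
    ss_residual: float

    _EPS = 1e-6

    def predict(self, n_patients: float, n_experts: float) -> float:
        p, e = float(n_patients), float(n_experts)
        design = np.array([1.0, p, e, p * p, e * e, p * e])
        return float(np.clip(design @ self.coefficients, self._EPS, 1.0 - self._EPS))


def fit_sizing_model(grid: Sequence[tuple[float, float, float]]) -> SizingModel:
    """Least-squares quadratic surface over (n_patients, n_experts, accuracy) rows."""
    arr = np.asarray(grid, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 6:
        raise ValueError("sizing grid needs >= 6 rows of (n_patients, n_experts, accuracy)")
    p, e, acc = arr[:, 0], arr[:, 1], arr[:, 2]
    design = np.column_stack([np.ones_like(p), p, e, p * p, e * e, p * e])
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("rank-deficient sizing design; grid must span both axes")
    coef, _, _, _ = np.linalg.lstsq(design, acc, rcond=None)
    resid = acc - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((acc - acc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SizingModel(coefficients=coef, r_squared=r2, ss_total=ss_tot, ss_residual=ss_res)


def predict_requirements(
    model: SizingModel,
    target_accuracy: float,
    max_experts: int = 25,
    max_patients: int = 2000,
) -> tuple[int, int]:
    """Smallest (n_patients, n_experts) whose predicted accuracy meets the target.

    Experts are treated as the costlier resource: the search minimises
    the expert count first, then the patient count.
    """
    if not 0.0 < target_accuracy < 1.0:
        raise ValueError(f"target accuracy must lie in (0, 1), got {target_accuracy}")
    for e in range(1, max_experts + 1):
        for p in range(1, max_patients + 1):
            if model.predict(p, e) >= target_accuracy:
                return p, e
    raise UnreachableTargetError(
        f"target accuracy {target_accuracy} unreachable within "
        f"{max_patients} patients x {max_experts} experts"
    )
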