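"""Compound classification benchmark: RF and Tanimoto-kernel SVM.

Protocol per activity class and trial: half the actives train the model (with
hyperparameters chosen by stratified 10-fold internal cross-validation and
grid search maximizing mean balanced accuracy), the other half are the
positive test instances, joined by three times as many negatives sampled from
a background pool. Performance is summarized from the confusion matrix as
balanced accuracy, Matthews correlation coefficient, F1, precision, and
recall; paired fingerprint comparisons use the two-sided Wilcoxon signed-rank
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "ClassificationResult",
    "metrics",
    "tanimoto_kernel",
    "run_classification",
    "wilcoxon_compare",
    "RF_GRID",
    "SVM_GRID",
]

#: hyperparameter grids of the benchmark protocol
RF_GRID = {"n_estimators": [25, 50, 100, 200, 400], "min_samples_split": [2, 3, 5, 10]}
SVM_GRID = {"C": [0.1, 1, 10, 50, 100, 200, 1000]}


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


class Metrics(NamedTuple):
    ba: float
    mcc: float
    f1: float
    precision: float
    recall: float


@dataclass(frozen=True)
class ClassificationResult:
    model: str
    fingerprint: str
    class_id: str
    trial: int
    counts: ConfusionCounts
    ba: float
    mcc: float
    f1: float
    precision: float
    recall: float
    chosen_hyperparameters: tuple


def metrics(counts: ConfusionCounts) -> Metrics:
    """Balanced accuracy, MCC, F1, precision, and recall from counts.

    BA = (TPR + TNR) / 2 with TPR = TP/(TP+FN), TNR = TN/(TN+FP);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0
    when any denominator factor vanishes; F1 = 2TP/(2TP+FP+FN). Requires at
    least one positive and one negative instance.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one positive and one negative instance")
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp)
    ba = 0.5 * (tpr + tnr)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tpr
    return Metrics(ba=float(ba), mcc=float(mcc), f1=float(f1),
                   precision=float(precision), recall=float(recall))


def tanimoto_kernel(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Tanimoto kernel matrix K[i, j] = Tc(X[i], Y[j]) for binary vectors.

    Symmetric with unit diagonal when ``Y is None`` (or ``Y is X``) and rows
    are non-zero; all-zero row pairs yield 0.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = X if Y is None else np.asarray(Y, dtype=np.float64)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"length mismatch: {X.shape[1]} vs {Y.shape[1]}")
    inter = X @ Y.T
    union = X.sum(axis=1)[:, None] + Y.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def _counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(y_true & y_pred)),
        TN=int(np.sum(~y_true & ~y_pred)),
        FP=int(np.sum(~y_true & y_pred)),
        FN=int(np.sum(y_true & ~y_pred)),
    )


def _make_estimator(model: str, random_state: int):
    if model == "RF":
        return RandomForestClassifier(random_state=random_state), RF_GRID
    if model == "SVM":
        return SVC(kernel=tanimoto_kernel, class_weight="balanced"), SVM_GRID
    raise ValueError(f"model must be 'SVM' or 'RF', got {model!r}")


def run_classification(
    actives: Sequence,
    negatives_pool: Sequence,
    fp_fn: Callable[[Sequence], np.ndarray],
    model: str = "SVM",
    n_trials: int = 20,
    seed: int = 0,
    negative_ratio: int = 3,
    cv_folds: int = 10,
    grid: dict | None = None,
    fingerprint: str = "csfp",
    class_id: str = "",
    permute_labels: bool = False,
) -> list[ClassificationResult]:
    """Run the classification benchmark for one activity class.

    Per trial: a random 50/50 split of the actives, internal grid search on
    training actives + ``negative_ratio``x training negatives, evaluation on
    held-out actives + fresh negatives. ``grid=None`` uses the protocol grid
    for the model. ``permute_labels=True`` shuffles training/test labels (a
    permutation-null control: MCC then centers at 0).
    """
    if len(actives) < 20:
        raise ValueError(f"class {class_id or '<unnamed>'}: need >= 20 actives")
    n_half = len(actives) // 2
    needed = 2 * negative_ratio * n_half
    if len(negatives_pool) < needed:
        raise ValueError(
            f"negatives pool too small: {len(negatives_pool)} < {needed}"
        )
    active_fps = np.asarray(fp_fn(list(actives)))
    pool_fps = np.asarray(fp_fn(list(negatives_pool)))

    trial_seeds = np.random.SeedSequence(seed).generate_state(n_trials) % (2**31)
    results = []
    for t in range(n_trials):
        ts = int(trial_seeds[t])
        rng = np.random.default_rng(ts)
        order = rng.permutation(len(actives))
        train_pos, test_pos = order[:n_half], order[n_half : 2 * n_half]
        neg_order = rng.permutation(len(negatives_pool))
        n_neg = negative_ratio * n_half
        train_neg, test_neg = neg_order[:n_neg], neg_order[n_neg : 2 * n_neg]

        X_train = np.vstack([active_fps[train_pos], pool_fps[train_neg]])
        y_train = np.concatenate([np.ones(n_half, dtype=int), np.zeros(n_neg, dtype=int)])
        X_test = np.vstack([active_fps[test_pos], pool_fps[test_neg]])
        y_test = np.concatenate([np.ones(n_half, dtype=int), np.zeros(n_neg, dtype=int)])
        if permute_labels:
            y_train = rng.permutation(y_train)
            y_test = rng.permutation(y_test)

        estimator, default_grid = _make_estimator(model, random_state=ts)
        search = GridSearchCV(
            estimator,
            grid if grid is not None else default_grid,
            scoring="balanced_accuracy",
            cv=StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=ts),
            n_jobs=1,
            refit=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X_train, y_train)
        counts = _counts_from_predictions(y_test, search.predict(X_test))
        m = metrics(counts)
        results.append(
            ClassificationResult(
                model=model,
                fingerprint=fingerprint,
                class_id=class_id,
                trial=t,
                counts=counts,
                ba=m.ba,
                mcc=m.mcc,
                f1=m.f1,
                precision=m.precision,
                recall=m.recall,
                chosen_hyperparameters=tuple(sorted(search.best_params_.items())),
            )
        )
    return results


def wilcoxon_compare(paired_a: Sequence[float], paired_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value over paired per-class values.

    All-zero differences are degenerate (no evidence of a difference): returns
    1.0 with a warning.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired sequences of equal length >= 5")
    if np.allclose(a, b):
        warnings.warn("all paired differences are zero; Wilcoxon test degenerate")
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
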