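"""Classifier training and panel evaluation.

``RidgeLogisticRegression`` is a deterministic Newton-iteration logistic
regression with a small L2 penalty on the coefficients (not the intercept);
the ridge term guarantees a finite optimum even on separable data, which
perfect methylation markers routinely produce.

Metrics follow the standard confusion-matrix definitions, reported per class
and as class-size-weighted averages (the "Average" row of a per-class
performance table).  AUC uses the rank (Mann-Whitney) formulation with ties
counted 1/2, so it is invariant under strictly monotone score transforms.
Cross-validation is stratified, with the confusion matrix pooled over
held-out folds at a probability cutoff of 0.5 and AUC computed from the
pooled held-out scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "RidgeLogisticRegression", "fit_logistic", "ConfusionCounts",
    "metrics_from_confusion", "weighted_average", "roc_auc",
    "cross_validate", "evaluate_external", "EvalReport",
]


class RidgeLogisticRegression(ClassifierMixin, BaseEstimator):
    """Binary logistic regression by Newton iterations with an L2 ridge.

    Parameters
    ----------
    l2 : float
        Ridge penalty on the coefficients (intercept unpenalized).
    tol : float
        Convergence when the largest coefficient change is below this.
    max_iter : int
        Iteration cap; exceeding it raises with the iteration trace.
    """

    def __init__(self, l2: float = 1e-4, tol: float = 1e-8, max_iter: int = 100):
        self.l2 = l2
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(self.classes_)}")
        t = (y == self.classes_[1]).astype(float)
        n, d = X.shape
        if min(int(t.sum()), int(n - t.sum())) < 2:
            raise ValueError("need at least 2 samples per class")
        w = np.zeros(d)
        b = 0.0
        trace = []
        for it in range(self.max_iter):
            eta = X @ w + b
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            s = np.maximum(p * (1.0 - p), 1e-10)
            grad_w = X.T @ (t - p) - self.l2 * w
            grad_b = float(np.sum(t - p))
            H = np.empty((d + 1, d + 1))
            H[:d, :d] = (X * s[:, None]).T @ X + self.l2 * np.eye(d)
            H[:d, d] = H[d, :d] = X.T @ s
            H[d, d] = s.sum()
            step = np.linalg.solve(H, np.concatenate([grad_w, [grad_b]]))
            w += step[:d]
            b += step[d]
            delta = float(np.max(np.abs(step)))
            trace.append(delta)
            if delta < self.tol:
                break
        else:
            raise RuntimeError(
                f"Newton iterations did not converge in {self.max_iter} steps; "
                f"last coefficient changes: {trace[-5:]}"
            )
        self.coef_ = w
        self.intercept_ = float(b)
        self.n_iter_ = it + 1
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        eta = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) >= 0).astype(int)]


def fit_logistic(X, y, l2: float = 1e-4) -> tuple[np.ndarray, float]:
    """Convenience wrapper: returns (coefficients, intercept)."""
    model = RidgeLogisticRegression(l2=l2).fit(X, y)
    return model.coef_, model.intercept_


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest confusion counts."""

    counts: dict[str, dict[str, int]]  # class -> {tp, fp, fn, tn}

    def __post_init__(self) -> None:
        totals = {c: sum(v.values()) for c, v in self.counts.items()}
        if len(set(totals.values())) > 1:
            raise ValueError("confusion counts disagree on the sample total")
        for c, v in self.counts.items():
            if min(v.values()) < 0:
                raise ValueError(f"negative count for class {c}")


def confusion_from_predictions(y_true, y_pred, classes) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    counts = {}
    for c in classes:
        t = y_true == c
        p = y_pred == c
        counts[str(c)] = {
            "tp": int(np.sum(t & p)), "fp": int(np.sum(~t & p)),
            "fn": int(np.sum(t & ~p)), "tn": int(np.sum(~t & ~p)),
        }
    return ConfusionCounts(counts)


def metrics_from_confusion(counts: ConfusionCounts) -> dict[str, dict[str, float]]:
    """TP rate, FP rate, precision and F-measure per class.

    precision is 0 when no positive predictions exist; F is 0 when precision
    and TP rate are both 0 (harmonic mean convention).
    """
    out = {}
    for c, v in counts.counts.items():
        tp, fp, fn, tn = v["tp"], v["fp"], v["fn"], v["tn"]
        tp_rate = tp / (tp + fn) if tp + fn else 0.0
        fp_rate = fp / (fp + tn) if fp + tn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f = (2 * precision * tp_rate / (precision + tp_rate)
             if precision + tp_rate else 0.0)
        out[c] = {"tp_rate": tp_rate, "fp_rate": fp_rate,
                  "precision": precision, "f_measure": f}
    return out


def weighted_average(per_class_metrics: dict[str, dict[str, float]],
                     class_sizes: dict[str, int]) -> dict[str, float]:
    """Class-size-weighted arithmetic mean of each metric."""
    total = sum(class_sizes.values())
    if total <= 0 or min(class_sizes.values()) <= 0:
        raise ValueError("class sizes must be positive")
    keys = next(iter(per_class_metrics.values())).keys()
    return {
        k: sum(class_sizes[c] / total * per_class_metrics[c][k]
               for c in per_class_metrics)
        for k in keys
    }


def roc_auc(scores, labels) -> float:
    """AUC as P(random positive outscores random negative), ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        raise TypeError("labels must be a boolean array (True = positive)")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores, labels) -> pd.DataFrame:
    """FPR/TPR points of the trapezoidal ROC curve."""
    fpr, tpr, thresholds = roc_curve(np.asarray(labels).astype(int), scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvalReport:
    per_class: dict[str, dict[str, float]]
    weighted: dict[str, float]
    auc: float
    confusion: dict[str, dict[str, int]]
    class_sizes: dict[str, int]
    seed: int | None = None
    folds: int | None = None
    fold_accuracy: list[float] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        c = next(iter(self.confusion.values()))
        return (c["tp"] + c["tn"]) / sum(c.values())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["accuracy"] = self.accuracy
        return d

    def to_table(self) -> pd.DataFrame:
        """Per-class rows plus the weighted Average row (TP rate, FP rate,
        Precision, F-measure, AUC)."""
        rows = []
        for c, m in self.per_class.items():
            rows.append([c, m["tp_rate"], m["fp_rate"], m["precision"],
                         m["f_measure"], self.auc])
        w = self.weighted
        rows.append(["Average", w["tp_rate"], w["fp_rate"], w["precision"],
                     w["f_measure"], self.auc])
        return pd.DataFrame(rows, columns=["class", "tp_rate", "fp_rate",
                                           "precision", "f_measure", "auc"])


def _report_from_scores(y_true, scores, classes, cutoff: float = 0.5,
                        seed=None, folds=None, fold_acc=None) -> EvalReport:
    """Build a report from positive-class probabilities.

    ``classes[1]`` is the positive class whose probability *scores* carries.
    """
    y_true = np.asarray(y_true)
    pred = np.asarray(classes)[(np.asarray(scores) >= cutoff).astype(int)]
    confusion = confusion_from_predictions(y_true, pred, classes)
    per_class = metrics_from_confusion(confusion)
    sizes = {str(c): int(np.sum(y_true == c)) for c in classes}
    pos = y_true == classes[1]
    auc = roc_auc(scores, pos) if 0 < pos.sum() < len(pos) else float("nan")
    for m in per_class.values():
        m["auc"] = auc
    present = {c: n for c, n in sizes.items() if n > 0}
    weighted = weighted_average({c: per_class[c] for c in present}, present)
    return EvalReport(per_class=per_class, weighted=weighted, auc=auc,
                      confusion=confusion.counts, class_sizes=sizes,
                      seed=seed, folds=folds,
                      fold_accuracy=list(fold_acc or []))


def cross_validate(
    X,
    y,
    folds: int = 10,
    seed: int = 0,
    l2: float = 1e-4,
    cutoff: float = 0.5,
) -> EvalReport:
    """Stratified k-fold cross-validation of the ridge logistic classifier.

    Fold assignment is random from *seed*; the confusion matrix is pooled
    over held-out folds at the probability *cutoff* and AUC comes from the
    pooled held-out scores.  Folds are reduced (with a warning) when the
    smallest class has fewer samples than *folds*.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    min_class = min(int(np.sum(y == c)) for c in classes)
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} samples; reducing folds "
            f"from {folds} to {min_class}"
        )
        folds = min_class
    if folds < 2:
        raise ValueError("need at least 2 folds (2 samples in each class)")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    fold_acc = []
    for train, test in skf.split(X, y):
        model = RidgeLogisticRegression(l2=l2).fit(X[train], y[train])
        p = model.predict_proba(X[test])[:, 1]
        scores[test] = p
        pred = model.classes_[(p >= cutoff).astype(int)]
        fold_acc.append(float(np.mean(pred == y[test])))
    return _report_from_scores(y, scores, classes, cutoff=cutoff,
                               seed=seed, folds=folds, fold_acc=fold_acc)


def evaluate_external(panel, beta_val: pd.DataFrame, y_val,
                      cutoff: float = 0.5) -> EvalReport:
    """Apply a frozen marker-panel classifier to an external beta matrix.

    *beta_val* is probes x samples and must contain every panel probe.
    """
    missing = [p for p in panel.probe_ids if p not in beta_val.index]
    if missing:
        raise KeyError(f"validation matrix lacks panel probe(s): {missing}")
    X = beta_val.loc[panel.probe_ids].to_numpy(dtype=float).T
    scores = panel.classifier.predict_proba(X)[:, 1]
    return _report_from_scores(np.asarray(y_val), scores,
                               panel.classifier.classes_, cutoff=cutoff)
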