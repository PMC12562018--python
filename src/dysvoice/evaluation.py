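"""Classification metrics, ROC/AUC and stratified cross-validation.

The metric suite follows the standard confusion-matrix definitions —
accuracy, precision, recall (sensitivity), specificity, F1 and the
Matthews correlation coefficient — with undefined ratios (zero
denominators) reported as *missing*, never silently coerced to 0.
ROC curves use a threshold sweep over the unique scores with the usual
tie convention (all tied scores cross the threshold together), AUC the
trapezoid rule; cross-validation is stratified k-fold with every item
predicted exactly once out-of-fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "roc_auc",
    "kfold_cv",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalReport:
    """Metric bundle for one evaluation run.

    Fields whose denominator was zero are ``None`` and listed in
    ``undefined``.  ``per_fold`` carries fold-level reports for CV runs,
    and ``fold_mean``/``fold_sd`` the across-fold summaries.
    """

    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    specificity: float | None = None
    f1: float | None = None
    mcc: float | None = None
    auc: float | None = None
    roc: tuple[tuple[float, ...], tuple[float, ...]] | None = None
    counts: ConfusionCounts | None = None
    undefined: list[str] = field(default_factory=list)
    per_fold: list["EvalReport"] = field(default_factory=list)
    fold_mean: dict[str, float] = field(default_factory=dict)
    fold_sd: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in
               ("accuracy", "precision", "recall", "specificity", "f1",
                "mcc", "auc")}
        out["undefined"] = list(self.undefined)
        if self.counts is not None:
            out["counts"] = asdict(self.counts)
        if self.per_fold:
            out["per_fold"] = [f.as_dict() for f in self.per_fold]
            out["fold_mean"] = dict(self.fold_mean)
            out["fold_sd"] = dict(self.fold_sd)
        return out


def _as_binary(y) -> np.ndarray:
    arr = np.asarray(y)
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1, False, True}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
    return arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count the four confusion cells (positive class = 1)."""
    t = _as_binary(y_true)
    p = _as_binary(y_pred)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred lengths differ")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts) -> EvalReport:
    """Evaluate the metric formulas exactly; zero-denominator ratios are
    flagged undefined."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    report = EvalReport(counts=c)
    undefined: list[str] = []

    report.accuracy = (c.tp + c.tn) / c.total

    def ratio(name: str, num: int, den: int) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    report.precision = ratio("precision", c.tp, c.tp + c.fp)
    report.recall = ratio("recall", c.tp, c.tp + c.fn)
    report.specificity = ratio("specificity", c.tn, c.tn + c.fp)
    if report.precision is None or report.recall is None or \
            (report.precision + report.recall) == 0:
        undefined.append("f1")
    else:
        report.f1 = (2 * report.precision * report.recall
                     / (report.precision + report.recall))
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        undefined.append("mcc")
    else:
        report.mcc = (c.tp * c.tn - c.fp * c.fn) / denom
    report.undefined = undefined
    return report


def roc_auc(y_true, scores) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """ROC curve by threshold sweep and trapezoid AUC.

    Tied scores cross each threshold simultaneously, which makes the
    all-equal-scores case integrate to exactly 0.5 and perfectly
    anti-separating scores to 0.0.
    """
    t = _as_binary(y_true)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("lengths differ")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    # group by unique descending score
    boundaries = np.flatnonzero(np.diff(s_sorted)) + 1
    groups = np.split(np.arange(s.size), boundaries)
    tpr = [0.0]
    fpr = [0.0]
    tp = fp = 0
    for g in groups:
        tp += int(t_sorted[g].sum())
        fp += g.size - int(t_sorted[g].sum())
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
    fpr_arr = np.asarray(fpr)
    tpr_arr = np.asarray(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return auc, (fpr_arr, tpr_arr)


def kfold_cv(builder, X, y, k: int = 10, seed: int = 0,
             scores_from="predict_proba") -> EvalReport:
    """Stratified k-fold cross-validation.

    ``builder()`` must return a fresh unfitted estimator with
    ``fit(X, y)`` and ``predict_proba``/``decision_function``.  Every
    item is predicted exactly once out-of-fold; the primary report pools
    the out-of-fold confusion counts, with per-fold metrics (mean +- sd)
    alongside.
    """
    y = _as_binary(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    class_sizes = np.bincount(y)
    if k > class_sizes.min():
        raise ValueError(f"k={k} exceeds the smaller class size "
                         f"({class_sizes.min()})")
    X_arr = np.asarray(X)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_scores = np.empty(y.size)
    oof_pred = np.empty(y.size, dtype=int)
    folds: list[EvalReport] = []
    for train_idx, test_idx in splitter.split(X_arr, y):
        model = builder()
        model.fit(X_arr[train_idx], y[train_idx])
        if scores_from == "predict_proba" and hasattr(model, "predict_proba"):
            proba = np.asarray(model.predict_proba(X_arr[test_idx]))
            score = proba[:, 1] if proba.ndim == 2 else proba
        else:
            score = np.asarray(model.decision_function(X_arr[test_idx]))
        oof_scores[test_idx] = score
        oof_pred[test_idx] = (score >= 0.5).astype(int) \
            if scores_from == "predict_proba" else (score >= 0).astype(int)
        folds.append(metrics(confusion(y[test_idx], oof_pred[test_idx])))

    report = metrics(confusion(y, oof_pred))
    auc, roc = roc_auc(y, oof_scores)
    report.auc = auc
    report.roc = (tuple(roc[0]), tuple(roc[1]))
    report.per_fold = folds
    for name in ("accuracy", "precision", "recall", "specificity", "f1", "mcc"):
        vals = [getattr(f, name) for f in folds if getattr(f, name) is not None]
        if vals:
            report.fold_mean[name] = float(np.mean(vals))
            report.fold_sd[name] = float(np.std(vals, ddof=0))
    return report
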