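"""Evaluation statistics for the grading and calibration studies.

Classification: confusion matrix, accuracy (%), macro-averaged recall (%)
and F1, one-vs-rest ROC AUC. Regression: Pearson r, RMSE (reported as
RMSEC on the calibration set and RMSEP on the prediction set) and
leave-one-out RMSECV. Descriptives: per-grade n/min/max/mean/variance/
SE-of-mean/MAD/CV with the sample (n-1) variance convention, under which
SE = sd/sqrt(n) and CV = sd/mean reproduce published grade tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EvaluationReport",
    "GradeStats",
    "classification_report",
    "confusion_matrix",
    "roc_auc",
    "pearson_r",
    "rmse",
    "loo_rmsecv",
    "grade_statistics",
]


@dataclass
class EvaluationReport:
    """Container for whichever statistics a pipeline run produces."""

    confusion: np.ndarray | None = None
    accuracy: float | None = None          # percent
    macro_recall: float | None = None      # percent
    macro_f1: float | None = None          # 0..1
    auc: dict[int, float] | None = None
    r_cal: float | None = None
    rmsec: float | None = None
    r_pre: float | None = None
    rmsep: float | None = None
    rmsecv: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if v is None or k == "extras":
                continue
            if isinstance(v, np.ndarray):
                out[k] = v.tolist()
            elif isinstance(v, dict):
                out[k] = {str(kk): float(vv) for kk, vv in v.items()}
            else:
                out[k] = float(v)
        out.update({k: v for k, v in self.extras.items()})
        return out


def confusion_matrix(
    true_grades: Sequence[int], pred_grades: Sequence[int], labels: Sequence[int] = (1, 2, 3)
) -> np.ndarray:
    t = np.asarray(true_grades, dtype=int)
    p = np.asarray(pred_grades, dtype=int)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != p.shape:
        raise ValueError("true and predicted grades must have equal length")
    idx = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for ti, pi in zip(t, p):
        cm[idx[ti], idx[pi]] += 1
    return cm


def classification_report(
    true_grades: Sequence[int], pred_grades: Sequence[int], labels: Sequence[int] = (1, 2, 3)
) -> EvaluationReport:
    """Accuracy (%), macro recall (%), macro F1 and the confusion matrix.

    Recall and F1 are macro-averaged over grades; a grade never predicted
    contributes an F1 of 0. Grades absent from the truth are excluded from
    the macro averages.
    """
    cm = confusion_matrix(true_grades, pred_grades, labels)
    total = cm.sum()
    accuracy = 100.0 * np.trace(cm) / total
    recalls, f1s = [], []
    for i in range(len(labels)):
        support = cm[i].sum()
        if support == 0:
            continue
        tp = cm[i, i]
        recall = tp / support
        predicted = cm[:, i].sum()
        precision = tp / predicted if predicted else 0.0
        f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
        recalls.append(recall)
        f1s.append(f1)
    return EvaluationReport(
        confusion=cm,
        accuracy=accuracy,
        macro_recall=100.0 * float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
    )


def _auc_binary(truth: np.ndarray, score: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling (equals trapezoidal ROC
    integration over all thresholds)."""
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    order = np.argsort(score, kind="stable")
    s = score[order]
    ranks = np.empty(truth.size)
    i = 0
    while i < s.size:
        j = i
        while j + 1 < s.size and s[j + 1] == s[i]:
            j += 1
        ranks[i : j + 1] = 0.5 * (i + j) + 1.0  # midrank, 1-based
        i = j + 1
    pos_ranks = ranks[truth[order] == 1]
    u = pos_ranks.sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(
    true_grades: Sequence[int], class_scores: np.ndarray, labels: Sequence[int] = (1, 2, 3)
) -> dict[int, float]:
    """One-vs-rest AUC per grade from continuous class scores (n x classes)."""
    t = np.asarray(true_grades, dtype=int)
    s = np.atleast_2d(np.asarray(class_scores, dtype=float))
    if s.shape != (t.size, len(labels)):
        raise ValueError(f"scores must be {t.size} x {len(labels)}")
    out = {}
    for j, lab in enumerate(labels):
        truth = (t == lab).astype(int)
        if truth.sum() in (0, t.size):
            raise ValueError(f"AUC undefined for grade {lab}: single-class truth")
        out[lab] = _auc_binary(truth, s[:, j])
    return out


def pearson_r(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Pearson product-moment correlation between measured and predicted."""
    a = np.asarray(y, dtype=float)
    b = np.asarray(y_hat, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    return float(np.corrcoef(a, b)[0, 1])


def rmse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    a = np.asarray(y, dtype=float)
    b = np.asarray(y_hat, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch between measured and predicted")
    return float(np.sqrt(np.mean((b - a) ** 2)))


def loo_rmsecv(
    features: np.ndarray,
    targets: Sequence[float],
    model_factory: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]],
    n_folds: int | None = None,
) -> float:
    """Leave-one-out (or k-fold, for expensive models) cross-validated RMSE.

    ``model_factory(train_x, train_y)`` must return a predictor callable.
    Folds are contiguous index blocks, deterministic.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("cross-validation needs at least 3 samples")
    if n_folds is None:
        n_folds = n
    folds = np.array_split(np.arange(n), n_folds)
    preds = np.empty(n)
    for fold_id, held in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        try:
            predictor = model_factory(x[mask], y[mask])
            preds[held] = np.asarray(predictor(x[held])).ravel()
        except Exception as exc:
            raise RuntimeError(f"model factory failed on fold {fold_id}: {exc}") from exc
    return rmse(y, preds)


@dataclass
class GradeStats:
    n: int
    minimum: float
    maximum: float
    mean: float
    variance: float
    se_of_mean: float
    mad: float
    cv: float


def grade_statistics(
    ssc: Sequence[float], grades: Sequence[int]
) -> dict[int, GradeStats]:
    """Per-grade descriptive statistics of SSC (°Brix).

    Sample (n-1) variance; SE = sd/sqrt(n); MAD = mean |x - mean|;
    CV = sd/mean (a fraction, not percent).
    """
    v = np.asarray(ssc, dtype=float)
    g = np.asarray(grades, dtype=int)
    if v.shape != g.shape:
        raise ValueError("ssc and grades must have equal length")
    if v.size == 0:
        raise ValueError("empty input")
    out = {}
    for lab in sorted(np.unique(g)):
        vals = v[g == lab]
        if vals.size == 0:
            raise ValueError(f"grade {lab} is empty")
        mean = float(vals.mean())
        var = float(vals.var(ddof=1)) if vals.size > 1 else 0.0
        sd = float(np.sqrt(var))
        out[int(lab)] = GradeStats(
            n=int(vals.size),
            minimum=float(vals.min()),
            maximum=float(vals.max()),
            mean=mean,
            variance=var,
            se_of_mean=sd / np.sqrt(vals.size),
            mad=float(np.mean(np.abs(vals - mean))),
            cv=sd / mean,
        )
    return out
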