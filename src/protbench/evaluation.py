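"""Metric suite and multi-seed statistical comparison.

The classification kernels are defined from the confusion-matrix ratios
(precision = TP/(TP+FP), recall = TP/(TP+FN)); ROC-AUC is the Mann-Whitney
pair statistic P(score_pos > score_neg) + 0.5 P(tie), computed from average
ranks; PR-AUC is step-wise average precision (no trapezoidal interpolation
by default, which is biased for PR curves — ``interpolate=True`` restores
the trapezoid for comparison).  Regression metrics are MSE, MAE, Spearman
rank correlation and the coefficient of determination.

Method comparison across replicate seeds uses a two-sided two-sample
Student's t-test (equal variances; Welch available).  The shipped
significance level is 0.05, configurable down to 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import TaskSpec
from .errors import (
    LengthMismatch,
    NoPositives,
    SingleClass,
    TooFewReplicates,
    ZeroVariance,
)

DEFAULT_ALPHA = 0.05


@dataclass
class MetricReport:
    values: Dict[str, float]
    n_samples: int
    task: str = ""
    seed: Optional[int] = None

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def _as_arrays(y_true, y_pred) -> Tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(y_true), np.asarray(y_pred)
    if a.shape != b.shape:
        raise LengthMismatch(f"shapes {a.shape} vs {b.shape}")
    return a, b


def confusion_counts(y_true, y_pred) -> Tuple[int, int, int, int]:
    """(TP, FP, TN, FN) for 0/1 labels and 0/1 predictions."""
    t, p = _as_arrays(y_true, y_pred)
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fn = int(np.sum((t == 1) & (p == 0)))
    return tp, fp, tn, fn


class PrecisionRecall(NamedTuple):
    precision: float
    recall: float
    precision_defined: bool = True
    recall_defined: bool = True


def precision_recall(counts: Tuple[int, int, int, int]) -> PrecisionRecall:
    """Precision and recall from (TP, FP, TN, FN); a zero denominator
    yields 0 with the matching ``*_defined`` flag cleared."""
    tp, fp, tn, fn = counts
    p_def, r_def = (tp + fp) > 0, (tp + fn) > 0
    return PrecisionRecall(
        precision=tp / (tp + fp) if p_def else 0.0,
        recall=tp / (tp + fn) if r_def else 0.0,
        precision_defined=bool(p_def),
        recall_defined=bool(r_def),
    )


def accuracy(y_true, y_pred) -> float:
    t, p = _as_arrays(y_true, y_pred)
    return float(np.mean(t == p))


def roc_auc(y_true, scores) -> float:
    """Mann-Whitney statistic: P(s_pos > s_neg) + 0.5 P(tie).

    Computed from average ranks, so tied scores are handled exactly and the
    value is invariant under any strictly monotone transform of the scores.
    """
    t, s = _as_arrays(y_true, scores)
    n_pos = int(np.sum(t == 1))
    n_neg = int(np.sum(t == 0))
    if n_pos == 0 or n_neg == 0:
        raise SingleClass("ROC-AUC needs both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def pr_auc(y_true, scores, interpolate: bool = False) -> float:
    """Average precision: sum over positive-introducing thresholds of
    precision x delta-recall.  Tied scores enter at one threshold."""
    t, s = _as_arrays(y_true, scores)
    n_pos = int(np.sum(t == 1))
    if n_pos == 0:
        raise NoPositives("PR-AUC needs at least one positive")
    order = np.argsort(-s, kind="mergesort")
    t_sorted, s_sorted = t[order], s[order]
    # threshold boundaries: last index of each distinct score
    boundary = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([boundary, [len(s_sorted) - 1]])
    tp = np.cumsum(t_sorted)[idx].astype(float)
    n_at = (idx + 1).astype(float)
    precision = tp / n_at
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    if interpolate:
        prev_precision = np.concatenate([[1.0], precision[:-1]])
        return float(np.sum((recall - prev_recall) *
                            (precision + prev_precision) / 2.0))
    return float(np.sum((recall - prev_recall) * precision))


def regression_metrics(y_true, y_pred) -> Tuple[float, float, float, float]:
    """(MSE, MAE, Spearman rho, R^2); constant truth raises ZeroVariance."""
    t, p = _as_arrays(np.asarray(y_true, float), np.asarray(y_pred, float))
    if t.size < 2:
        raise LengthMismatch("regression metrics need N >= 2")
    mse = float(np.mean((t - p) ** 2))
    mae = float(np.mean(np.abs(t - p)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise ZeroVariance("constant y_true: rho and R^2 undefined")
    r2 = 1.0 - float(np.sum((t - p) ** 2)) / ss_tot
    if np.ptp(p) == 0.0:
        rho = 0.0  # constant predictions carry no ranking information
    else:
        rho = float(stats.spearmanr(t, p).statistic)
    return mse, mae, rho, r2


def _binary_f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def macro_f1(y_true, y_pred, num_classes: int) -> float:
    """Unweighted mean of one-vs-rest F1 over all declared classes; classes
    absent from both truth and prediction contribute F1 = 0."""
    t, p = _as_arrays(y_true, y_pred)
    f1s = []
    for c in range(num_classes):
        tp = int(np.sum((t == c) & (p == c)))
        fp = int(np.sum((t != c) & (p == c)))
        fn = int(np.sum((t == c) & (p != c)))
        f1s.append(_binary_f1(tp, fp, fn))
    return float(np.mean(f1s))


# -- task-conditioned report ---------------------------------------------

def _binary_report(y_true, scores, y_pred) -> Dict[str, float]:
    tp, fp, tn, fn = confusion_counts(y_true, y_pred)
    pr = precision_recall((tp, fp, tn, fn))
    return {
        "roc_auc": roc_auc(y_true, scores),
        "pr_auc": pr_auc(y_true, scores),
        "macro_f1": macro_f1(y_true, y_pred, 2),
        "accuracy": accuracy(y_true, y_pred),
        "precision": pr.precision,
        "recall": pr.recall,
    }


def compute_metrics(task_spec: TaskSpec, predictions: pd.DataFrame,
                    truth: Sequence) -> MetricReport:
    """Score a prediction table against labeled records.

    Residue-level tasks pool all real residues across sequences before
    computing (micro pooling).  Regression reports {mse, mae, spearman, r2};
    binary reports AUCs, macro F1 and threshold metrics; multiclass reports
    accuracy and macro F1.
    """
    by_id = {r.id: r for r in truth}
    if task_spec.level == "residue":
        y_true, y_pred, scores = [], [], []
        for row in predictions.itertuples(index=False):
            rec = by_id[row.id]
            y_true.append(rec.residue_labels[row.position])
            y_pred.append(int(row.pred))
            if task_spec.num_classes == 2:
                scores.append(float(getattr(row, "prob_1")))
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        if task_spec.num_classes == 2:
            values = _binary_report(y_true, np.asarray(scores), y_pred)
        else:
            values = {"accuracy": accuracy(y_true, y_pred),
                      "macro_f1": macro_f1(y_true, y_pred, task_spec.num_classes)}
        return MetricReport(values, n_samples=len(y_true), task=task_spec.name)

    ids = predictions["id"].tolist()
    y_true = np.asarray([by_id[i].label for i in ids])
    if task_spec.objective == "regression":
        mse, mae, rho, r2 = regression_metrics(
            y_true, predictions["pred"].to_numpy(float))
        values = {"mse": mse, "mae": mae, "spearman": rho, "r2": r2}
    elif task_spec.objective == "binary":
        scores = (predictions["prob"] if "prob" in predictions.columns
                  else predictions["prob_1"]).to_numpy(float)
        values = _binary_report(y_true, scores,
                                predictions["pred"].to_numpy(int))
    else:
        y_pred = predictions["pred"].to_numpy(int)
        values = {"accuracy": accuracy(y_true, y_pred),
                  "macro_f1": macro_f1(y_true, y_pred, task_spec.num_classes)}
    return MetricReport(values, n_samples=len(y_true), task=task_spec.name)


#: Headline metric per task shape, used for history curves and leaderboards.
def primary_metric(task_spec: TaskSpec) -> str:
    if task_spec.objective == "regression":
        return "r2" if task_spec.arity == "pair" else "spearman"
    if task_spec.objective == "binary":
        return "roc_auc"
    return "accuracy"


# -- multi-seed comparison ------------------------------------------------

@dataclass
class ComparisonResult:
    method_a: str
    method_b: str
    values_a: Tuple[float, ...]
    values_b: Tuple[float, ...]
    t_statistic: float
    p_value: float
    alpha: float
    verdict: str  # significant | not_significant


def compare_methods(values_a: Sequence[float], values_b: Sequence[float],
                    alpha: float = DEFAULT_ALPHA, welch: bool = False,
                    name_a: str = "A", name_b: str = "B") -> ComparisonResult:
    """Two-sided two-sample t-test on replicate metric values.

    Student's (equal-variance) test by default, Welch via flag.  Degenerate
    zero-variance inputs are handled explicitly: identical means give
    t = 0, p = 1; separated means with zero variance give p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise TooFewReplicates("need >= 2 replicate values per method")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(res.statistic), float(res.pvalue)
    verdict = "significant" if p < alpha else "not_significant"
    return ComparisonResult(name_a, name_b, tuple(a), tuple(b),
                            t_stat, p, alpha, verdict)
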