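"""Evaluation suite: confusion matrix, one-vs-rest rates, kappa, AUC.

Multiclass metrics are computed by one-vs-rest reduction of the confusion
matrix: for class k, TP are beats of class k predicted k, FP beats of
other classes predicted k, FN beats of class k predicted otherwise, and
TN the rest.  Per-class sensitivity (= recall), specificity, precision
and F1 are macro-averaged (unweighted mean over classes); micro averages
are reported alongside since overall accuracy equals micro recall.

Cohen's kappa corrects the observed agreement Po (= accuracy) by the
chance agreement Pe implied by the marginals:
kappa = (Po - Pe) / (1 - Pe).

AUC is the rank statistic of class-vs-rest scores (ties contribute 1/2),
equivalent to trapezoidal integration of the ROC curve.

Zero-denominator rates are reported as 0 and flagged degenerate so small
or single-class evaluations never crash.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


class PairingError(ValueError):
    """Raised when truth and prediction vectors disagree in length."""


class EmptyEvaluationError(ValueError):
    """Raised when metrics are requested for zero samples."""


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K count matrix; rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise PairingError(
            f"length mismatch: {y_true.size} true vs {y_pred.size} predicted"
        )
    if y_true.size and (
        y_true.min() < 0 or y_pred.min() < 0
        or y_true.max() >= n_classes or y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    cm = np.bincount(
        y_true * n_classes + y_pred, minlength=n_classes * n_classes
    )
    return cm.reshape(n_classes, n_classes)


@dataclass(frozen=True)
class BinaryRates:
    """One-vs-rest counts and rates for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    degenerate: bool  # True when any rate had a 0/0 denominator


def binary_rates(cm: np.ndarray, class_id: int) -> BinaryRates:
    """One-vs-rest reduction of a confusion matrix for one class."""
    cm = np.asarray(cm)
    total = int(cm.sum())
    if total == 0:
        raise EmptyEvaluationError("confusion matrix is empty")
    tp = int(cm[class_id, class_id])
    fn = int(cm[class_id].sum() - tp)
    fp = int(cm[:, class_id].sum() - tp)
    tn = total - tp - fn - fp
    degenerate = False

    def _rate(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    se = _rate(tp, tp + fn)
    sp = _rate(tn, tn + fp)
    pr = _rate(tp, tp + fp)
    f1 = _rate_f1(pr, se)
    if pr + se == 0:
        degenerate = True
    return BinaryRates(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / total,
        sensitivity=se, specificity=sp, precision=pr, recall=se, f1=f1,
        degenerate=degenerate,
    )


def _rate_f1(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    po: float
    pe: float
    degenerate: bool = False


def cohen_kappa(y_true, y_pred) -> KappaResult:
    """Chance-corrected agreement: kappa = (Po - Pe) / (1 - Pe)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise PairingError("truth and prediction lengths differ")
    n = y_true.size
    if n == 0:
        raise EmptyEvaluationError("cannot compute kappa of zero samples")
    k = int(max(y_true.max(), y_pred.max())) + 1
    cm = confusion_matrix(y_true, y_pred, k)
    po = float(np.trace(cm)) / n
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / n**2
    if pe >= 1.0:
        # all mass in one cell of the marginals: agreement is forced
        return KappaResult(1.0 if po == 1.0 else 0.0, po, pe, degenerate=True)
    return KappaResult((po - pe) / (1.0 - pe), po, pe)


def roc_auc_ovr(y_true, scores) -> tuple[float, dict[int, float], list[int]]:
    """Macro one-vs-rest AUC by the rank (Mann-Whitney) statistic.

    Returns (macro_auc, per-class AUCs, classes skipped because they have
    no positives or no negatives in ``y_true``).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != y_true.size:
        raise PairingError("scores must be (n_samples, n_classes)")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    per_class: dict[int, float] = {}
    skipped: list[int] = []
    for c in range(scores.shape[1]):
        pos = y_true == c
        n_pos = int(pos.sum())
        n_neg = y_true.size - n_pos
        if n_pos == 0 or n_neg == 0:
            skipped.append(c)
            continue
        ranks = rankdata(scores[:, c])  # average ranks: ties count 1/2
        rank_sum = ranks[pos].sum()
        per_class[c] = (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    if not per_class:
        raise EmptyEvaluationError("no class has both positives and negatives")
    macro = float(np.mean(list(per_class.values())))
    return macro, per_class, skipped


@dataclass
class MetricsReport:
    """Full evaluation: accuracy, per-class and averaged rates, kappa, AUC."""

    accuracy: float
    per_class: dict[int, BinaryRates]
    macro_sensitivity: float
    macro_specificity: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_f1: float
    kappa: KappaResult
    confusion: np.ndarray
    auc_macro: float | None = None
    auc_per_class: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro": {
                "sensitivity": self.macro_sensitivity,
                "specificity": self.macro_specificity,
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "micro_f1": self.micro_f1,
            "kappa": {
                "kappa": self.kappa.kappa,
                "po": self.kappa.po,
                "pe": self.kappa.pe,
            },
            "auc_macro": self.auc_macro,
            "auc_per_class": {str(k): v for k, v in self.auc_per_class.items()},
            "per_class": {
                str(c): {
                    "tp": r.tp, "tn": r.tn, "fp": r.fp, "fn": r.fn,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "precision": r.precision,
                    "f1": r.f1,
                }
                for c, r in self.per_class.items()
            },
            "confusion": self.confusion.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def multiclass_report(
    y_true, y_pred, scores=None, n_classes: int | None = None
) -> MetricsReport:
    """Evaluate predictions; AUC is included only when scores are given."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise EmptyEvaluationError("cannot evaluate zero samples")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = confusion_matrix(y_true, y_pred, n_classes)
    present = np.nonzero(cm.sum(axis=1) > 0)[0]
    per_class = {int(c): binary_rates(cm, int(c)) for c in range(n_classes)}
    rates = [per_class[int(c)] for c in present]  # macro over present classes
    accuracy = float(np.trace(cm)) / y_true.size
    micro_tp = int(np.trace(cm))
    micro_fp = int(cm.sum() - np.trace(cm))
    micro_pr = micro_tp / (micro_tp + micro_fp)  # == accuracy == micro recall
    report = MetricsReport(
        accuracy=accuracy,
        per_class=per_class,
        macro_sensitivity=float(np.mean([r.sensitivity for r in rates])),
        macro_specificity=float(np.mean([r.specificity for r in rates])),
        macro_precision=float(np.mean([r.precision for r in rates])),
        macro_recall=float(np.mean([r.recall for r in rates])),
        macro_f1=float(np.mean([r.f1 for r in rates])),
        micro_f1=micro_pr,
        kappa=cohen_kappa(y_true, y_pred),
        confusion=cm,
    )
    if scores is not None:
        macro_auc, per_auc, _ = roc_auc_ovr(y_true, scores)
        report.auc_macro = macro_auc
        report.auc_per_class = per_auc
    return report
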