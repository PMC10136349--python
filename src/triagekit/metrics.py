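"""Confusion matrix and multiclass evaluation formulas.

For K classes, the K x K confusion matrix (rows = true class, columns =
predicted) yields one-vs-rest TP/FP/FN/TN per class, from which:

* per-class precision P_i = TP_i/(TP_i + FP_i) and recall
  R_i = TP_i/(TP_i + FN_i) (0, flagged, when the denominator is 0);
* macro precision/recall: unweighted means over classes; macro F1: the
  harmonic mean of macro precision and macro recall;
* weighted precision/recall: Σ w_i·metric_i with w_i = n_i/N the class's
  sample share; weighted F1: harmonic mean of the two;
* top-1 accuracy = trace/N, the headline accuracy;
* one-vs-rest averaged binary accuracy
  Σ_i(TP_i + TN_i) / Σ_i(TP_i + TN_i + FP_i + FN_i), reported separately
  (for single-label data it equals 1 − 2(1 − top1)/K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "EvaluationReport", "confusion_matrix", "evaluate"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (counts < 0).any():
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-class (TP, FP, FN, TN) as length-K arrays."""
        tp = np.diag(self.counts).astype(np.int64)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion_matrix(true_ids, pred_ids, k: int) -> ConfusionMatrix:
    """Tally (true, predicted) pairs; ids are 1-based in 1..k."""
    true_ids = np.asarray(true_ids, dtype=np.int64)
    pred_ids = np.asarray(pred_ids, dtype=np.int64)
    if true_ids.shape != pred_ids.shape or true_ids.ndim != 1:
        raise ValueError("true_ids and pred_ids must be 1-D and equally long")
    for name, ids in (("true", true_ids), ("pred", pred_ids)):
        if ids.size and (ids.min() < 1 or ids.max() > k):
            raise ValueError(f"{name} ids must lie in 1..{k}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (true_ids - 1, pred_ids - 1), 1)
    return ConfusionMatrix(counts)


@dataclass
class EvaluationReport:
    """All evaluation indicators derived from one confusion matrix."""

    accuracy_top1: float
    accuracy_ovr: float  # one-vs-rest averaged binary accuracy
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray
    precision_macro: float
    recall_macro: float
    f1_macro: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    class_weights: np.ndarray  # w_i = n_i / N
    undefined_precision: list[int] = field(default_factory=list)  # 1-based ids
    undefined_recall: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy_top1,
            "accuracy_ovr": self.accuracy_ovr,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
        }

    def row(self, method: str = "") -> str:
        d = self.as_dict()
        cells = "\t".join(f"{d[k]:.4f}" for k in (
            "accuracy", "precision_macro", "recall_macro", "f1_macro",
            "precision_weighted", "recall_weighted", "f1_weighted"))
        return f"{method}\t{cells}" if method else cells


def _harmonic(p: float, r: float) -> float:
    return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


def evaluate(cm: ConfusionMatrix) -> EvaluationReport:
    """Compute every indicator from a confusion matrix with N > 0 rows."""
    if cm.total == 0:
        raise ValueError("cannot evaluate an empty confusion matrix")
    tp, fp, fn, tn = cm.one_vs_rest()
    k, n = cm.k, cm.total

    undefined_p = [i + 1 for i in range(k) if tp[i] + fp[i] == 0]
    undefined_r = [i + 1 for i in range(k) if tp[i] + fn[i] == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)

    weights = cm.counts.sum(axis=1) / n

    p_macro = float(precision.mean())
    r_macro = float(recall.mean())
    p_weighted = float((weights * precision).sum())
    r_weighted = float((weights * recall).sum())

    return EvaluationReport(
        accuracy_top1=float(np.trace(cm.counts) / n),
        accuracy_ovr=float((tp + tn).sum() / (tp + tn + fp + fn).sum()),
        precision_per_class=precision,
        recall_per_class=recall,
        precision_macro=p_macro,
        recall_macro=r_macro,
        f1_macro=_harmonic(p_macro, r_macro),
        precision_weighted=p_weighted,
        recall_weighted=r_weighted,
        f1_weighted=_harmonic(p_weighted, r_weighted),
        class_weights=weights,
        undefined_precision=undefined_p,
        undefined_recall=undefined_r,
    )
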