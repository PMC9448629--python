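"""Evaluation: precision/recall/F1 from confusion counts, one-vs-rest
tallies on top-1 predictions, and k-fold cross-validation.

Counts follow the AIR/DR/CDR bookkeeping: AIR = TP + FN (truly relevant),
DR = TP + FP (retrieved), CDR = TP + TN (consistent decisions).  Metrics
with a zero denominator are reported as 0 with an explicit undefined flag
rather than raising, so cross-validation aggregation stays robust.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import pipeline
from .records import CONSTITUTIONS, MedicalRecord

__all__ = [
    "EvaluationCounts",
    "Metrics",
    "compute_metrics",
    "confusion_counts",
    "per_class_evaluation",
    "cross_validate",
    "CVResult",
]


@dataclass(frozen=True)
class EvaluationCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def air(self) -> int:
        """Samples truly in the positive class: TP + FN."""
        return self.tp + self.fn

    @property
    def dr(self) -> int:
        """Samples the model retrieved as positive: TP + FP."""
        return self.tp + self.fp

    @property
    def cdr(self) -> int:
        """Decisions consistent with the truth: TP + TN."""
        return self.tp + self.tn


@dataclass(frozen=True)
class Metrics:
    """Precision, recall and F1 as fractions in [0, 1].

    ``precision_defined`` / ``recall_defined`` are False when the respective
    denominator was zero (the value is then reported as 0).
    """

    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True

    def as_percent(self, ndigits: int = 2) -> dict:
        return {
            "P": round(self.precision * 100, ndigits),
            "R": round(self.recall * 100, ndigits),
            "F1": round(self.f1 * 100, ndigits),
        }


def compute_metrics(counts: EvaluationCounts) -> Metrics:
    """P = TP/DR, R = TP/AIR, F1 = 2PR/(P+R); F1 = 0 when P + R = 0."""
    p_def = counts.dr > 0
    r_def = counts.air > 0
    p = counts.tp / counts.dr if p_def else 0.0
    r = counts.tp / counts.air if r_def else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return Metrics(p, r, f1, p_def, r_def)


def confusion_counts(predictions: Sequence, truths: Sequence,
                     positive_class: str) -> EvaluationCounts:
    """One-vs-rest tally of top-1 predictions against true labels.

    ``predictions`` entries may be a label token or None (no prediction).
    """
    if len(predictions) != len(truths):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths")
    tp = fp = fn = tn = 0
    for pred, truth in zip(predictions, truths):
        pred_pos = pred == positive_class
        true_pos = truth == positive_class
        if pred_pos and true_pos:
            tp += 1
        elif pred_pos:
            fp += 1
        elif true_pos:
            fn += 1
        else:
            tn += 1
    return EvaluationCounts(tp, fp, fn, tn)


def per_class_evaluation(predictions: Sequence, truths: Sequence,
                         classes: Sequence[str] = CONSTITUTIONS) -> dict:
    """Per-class counts/metrics plus their macro average.

    The macro average runs over the classes actually present in ``truths``
    (classes with AIR = 0 contribute no information).
    """
    per_class = {}
    macro_p, macro_r, macro_f = [], [], []
    present = {t for t in truths}
    for cls in classes:
        counts = confusion_counts(predictions, truths, cls)
        metrics = compute_metrics(counts)
        per_class[cls] = (counts, metrics)
        if cls in present:
            macro_p.append(metrics.precision)
            macro_r.append(metrics.recall)
            macro_f.append(metrics.f1)
    macro = Metrics(
        float(np.mean(macro_p)) if macro_p else 0.0,
        float(np.mean(macro_r)) if macro_r else 0.0,
        float(np.mean(macro_f)) if macro_f else 0.0,
    )
    return {"per_class": per_class, "macro": macro}


@dataclass
class CVResult:
    fold_metrics: list  # Metrics per fold (macro-averaged)
    mean_precision: float
    mean_recall: float
    mean_f1: float
    fold_sizes: list = field(default_factory=list)


def cross_validate(records: Sequence[MedicalRecord], k: int = 10, seed: int = 0,
                   stratified: bool = True,
                   train_fn: Callable | None = None,
                   classify_fn: Callable | None = None,
                   **train_kwargs) -> CVResult:
    """Seeded k-fold cross-validation of the train→classify pipeline.

    Each fold trains on the other k-1 folds and classifies the held-out
    records by their symptoms; fold metrics are the macro-averaged one-vs-rest
    precision/recall/F1 on top-1 predictions.  Folds are stratified by primary
    constitution unless ``stratified=False``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(records) < k:
        raise ValueError(f"need at least k={k} records, got {len(records)}")
    train_fn = train_fn or pipeline.train
    classify_fn = classify_fn or pipeline.classify
    labels = [rec.primary_constitution.token for rec in records]
    idx = np.arange(len(records))
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx, labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx)
    fold_metrics: list[Metrics] = []
    fold_sizes: list[int] = []
    for train_idx, test_idx in splits:
        train_records = [records[i] for i in train_idx]
        rulebase = train_fn(train_records, **train_kwargs)
        preds = []
        truths = []
        for i in test_idx:
            rec = records[i]
            preds.append(classify_fn(rec.symptoms, rulebase).top1)
            truths.append(rec.primary_constitution.token)
        fold_metrics.append(per_class_evaluation(preds, truths)["macro"])
        fold_sizes.append(len(test_idx))
    return CVResult(
        fold_metrics,
        float(np.mean([m.precision for m in fold_metrics])),
        float(np.mean([m.recall for m in fold_metrics])),
        float(np.mean([m.f1 for m in fold_metrics])),
        fold_sizes,
    )
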