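"""Classification and ranking metrics for PPI article triage.

Binary metrics (accuracy, specificity, sensitivity, precision, F1, MCC)
are computed from a 2x2 confusion matrix with +1 as the positive class:

    F1  = 2 P R / (P + R),     P = TP/(TP+FP),  R = TP/(TP+FN)
    MCC = (TP TN - FP FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Ranking metrics operate on a deterministic ranked list (descending score,
ties broken by ascending doc_id):

* average precision — mean of the precision at each relevant document's
  rank (the non-interpolated area under the P/R curve);
* AUC iP/R — mean of *interpolated* precision at each relevant document's
  recall point, where ip(r) = max precision at any recall >= r; always
  >= average precision;
* P@n — precision within the top n ranks.

An unbalanced test set leaves accuracy high even for trivial predictors,
which is why F1, MCC and the ranking measures are the headline numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "ConfusionMatrix",
    "RankedList",
    "confusion",
    "basic_rates",
    "f1",
    "mcc",
    "rank_documents",
    "average_precision",
    "auc_ipr",
    "precision_at",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one example")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(gold: Mapping[str, int], predicted: Mapping[str, int]) -> ConfusionMatrix:
    """Standard 2x2 counts; gold and predicted must cover the same ids."""
    if set(gold) != set(predicted):
        diff = sorted(set(gold) ^ set(predicted))
        raise ValueError(f"gold/predicted id mismatch: {diff[:10]}")
    tp = fp = fn = tn = 0
    for doc_id, g in gold.items():
        p = predicted[doc_id]
        if g == +1:
            tp += p == +1
            fn += p != +1
        else:
            fp += p == +1
            tn += p != +1
    return ConfusionMatrix(tp, fp, fn, tn)


def _rate(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def basic_rates(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, specificity (TNR), sensitivity (recall) and precision."""
    return {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "specificity": _rate(cm.tn, cm.tn + cm.fp, "specificity"),
        "sensitivity": _rate(cm.tp, cm.tp + cm.fn, "sensitivity"),
        "precision": _rate(cm.tp, cm.tp + cm.fp, "precision"),
    }


def f1(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall; 0 when P + R = 0."""
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        return 0.0
    return 2 * cm.tp / denom


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


@dataclass
class RankedList:
    """Doc ids ordered by descending score; ties broken by ascending id."""

    doc_ids: list[str]
    gold: list[int]  # +1 / -1 aligned with doc_ids

    def __post_init__(self) -> None:
        if len(self.doc_ids) != len(self.gold):
            raise ValueError("doc_ids and gold labels differ in length")

    @property
    def n_positive(self) -> int:
        return sum(1 for g in self.gold if g == +1)


def rank_documents(
    scores: Mapping[str, float], gold: Mapping[str, int]
) -> RankedList:
    if set(scores) != set(gold):
        diff = sorted(set(scores) ^ set(gold))
        raise ValueError(f"score/label id mismatch: {diff[:10]}")
    order = sorted(scores, key=lambda d: (-scores[d], d))
    return RankedList(order, [gold[d] for d in order])


def average_precision(ranked: RankedList) -> float:
    """Mean precision at the ranks where relevant documents appear."""
    if ranked.n_positive == 0:
        raise ValueError("average precision requires at least one positive")
    hits = 0
    total = 0.0
    for rank, g in enumerate(ranked.gold, start=1):
        if g == +1:
            hits += 1
            total += hits / rank
    return total / hits


def auc_ipr(ranked: RankedList, convention: str = "recall_points") -> float:
    """Area under the interpolated precision/recall curve.

    ``recall_points`` (default) averages ip(r) = max precision at any
    recall >= r over each positive's recall point.  ``trapezoid``
    integrates the interpolated curve over [0, 1] instead.
    """
    if ranked.n_positive == 0:
        raise ValueError("AUC iP/R requires at least one positive")
    n_pos = ranked.n_positive
    precisions: list[float] = []  # precision at each positive's rank
    hits = 0
    for rank, g in enumerate(ranked.gold, start=1):
        if g == +1:
            hits += 1
            precisions.append(hits / rank)
    # interpolate: max precision at this or any later recall point
    interpolated = list(precisions)
    for i in range(len(interpolated) - 2, -1, -1):
        interpolated[i] = max(interpolated[i], interpolated[i + 1])
    if convention == "recall_points":
        return sum(interpolated) / n_pos
    if convention == "trapezoid":
        area = 0.0
        prev_recall = 0.0
        for i, ip in enumerate(interpolated, start=1):
            recall = i / n_pos
            area += (recall - prev_recall) * ip
            prev_recall = recall
        return area
    raise ValueError(f"unknown convention {convention!r}")


def precision_at(ranked: RankedList, n: int) -> float:
    """Fraction of positives within the top n ranks."""
    if not 1 <= n <= len(ranked.gold):
        raise ValueError(f"n must lie in [1, {len(ranked.gold)}]")
    return sum(1 for g in ranked.gold[:n] if g == +1) / n


def metrics_report(
    scores: Mapping[str, float],
    predicted: Mapping[str, int],
    gold: Mapping[str, int],
    at_ranks: Sequence[int] = (100, 200, 300),
) -> dict[str, float]:
    """The full metric suite from scores, binarized predictions and gold."""
    cm = confusion(gold, predicted)
    report = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
    report.update(basic_rates(cm))
    report["f1"] = f1(cm)
    report["mcc"] = mcc(cm)
    ranked = rank_documents(scores, gold)
    if ranked.n_positive > 0:
        report["average_precision"] = average_precision(ranked)
        report["auc_ipr"] = auc_ipr(ranked)
    for n in at_ranks:
        if n <= len(ranked.doc_ids):
            report[f"p_at_{n}"] = precision_at(ranked, n)
    return report
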