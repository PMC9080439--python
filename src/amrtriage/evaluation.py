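"""Confusion matrices, per-class metrics, and labeling-agreement reports.

Class 0 (relevant) is the positive class throughout: ``tp`` counts gold-
relevant documents predicted relevant, ``tn`` gold-irrelevant documents
predicted irrelevant.  Metrics are reported both at full precision and
rounded — half-up to two decimals for ratios, to the nearest integer for
percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .labeling import IRRELEVANT, RELEVANT, LabelRecord

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "AgreementReport",
    "confusion",
    "metrics",
    "label_agreement",
    "format_report",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (0.825 -> 0.83)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def round_pct(x: float) -> int:
    """Round a percentage half-up to the nearest integer."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with class 0 (relevant) as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def gold_positives(self) -> int:
        return self.tp + self.fn

    @property
    def gold_negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    #: set when a zero denominator forced a metric to 0
    zero_division: bool = False


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[int, ClassMetrics]
    accuracy: float

    def rounded(self) -> dict:
        """Two-decimal view of the report, in the layout of a per-class table."""
        out = {}
        for cls, m in sorted(self.per_class.items()):
            out[cls] = {
                "precision": round2(m.precision),
                "recall": round2(m.recall),
                "f1": round2(m.f1),
                "support": m.support,
            }
        out["accuracy"] = round2(self.accuracy)
        return out

    def to_json(self, cm: ConfusionMatrix | None = None) -> str:
        payload = {
            "accuracy": self.accuracy,
            "per_class": {
                str(cls): vars(m) for cls, m in sorted(self.per_class.items())
            },
            "rounded": {str(k): v for k, v in self.rounded().items()},
        }
        if cm is not None:
            payload["confusion"] = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class AgreementReport:
    """Agreement of an automatic labeling with the expert gold labels."""

    n_agree: int
    n_total: int
    pct_overall: float
    pct_relevant: float
    pct_irrelevant: float

    def rounded(self) -> dict[str, int]:
        return {
            "overall": round_pct(self.pct_overall),
            "relevant": round_pct(self.pct_relevant),
            "irrelevant": round_pct(self.pct_irrelevant),
        }


def _paired(pred: list[LabelRecord], gold: list[LabelRecord]) -> list[tuple[int, int]]:
    pred_by_id = {r.doc_id: r.label for r in pred}
    gold_by_id = {r.doc_id: r.label for r in gold}
    if len(pred_by_id) != len(pred) or len(gold_by_id) != len(gold):
        raise ValueError("duplicate doc_ids in label list")
    if pred_by_id.keys() != gold_by_id.keys():
        diff = sorted(pred_by_id.keys() ^ gold_by_id.keys())
        raise ValueError(f"doc_id mismatch between predictions and gold: {diff}")
    return [(pred_by_id[i], g) for i, g in gold_by_id.items()]


def confusion(pred: list[LabelRecord], gold: list[LabelRecord]) -> ConfusionMatrix:
    """Count the 2x2 confusion matrix of predictions against gold labels.

    Both lists must cover exactly the same documents; the result does not
    depend on list order.
    """
    tp = fp = fn = tn = 0
    for p, g in _paired(pred, gold):
        if g == RELEVANT:
            tp += p == RELEVANT
            fn += p == IRRELEVANT
        else:
            tn += p == IRRELEVANT
            fp += p == RELEVANT
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _prf(tp: int, fp: int, fn: int, support: int) -> ClassMetrics:
    zero = False
    if tp + fp == 0:
        precision, zero = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, zero = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, zero = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassMetrics(precision=precision, recall=recall, f1=f1,
                        support=support, zero_division=zero)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class precision/recall/F1 and overall accuracy from a 2x2 matrix.

    For class 1 the roles of the counts swap: its "true positives" are the
    ``tn`` cell, and so on.  Zero denominators yield 0 with a flag instead of
    an error.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    report = {
        RELEVANT: _prf(cm.tp, cm.fp, cm.fn, support=cm.gold_positives),
        IRRELEVANT: _prf(cm.tn, cm.fn, cm.fp, support=cm.gold_negatives),
    }
    return MetricsReport(per_class=report, accuracy=(cm.tp + cm.tn) / cm.total)


def label_agreement(auto: list[LabelRecord], gold: list[LabelRecord]) -> AgreementReport:
    """Percentage agreement of automatic labels with gold, overall and per class."""
    pairs = _paired(auto, gold)
    n_agree = sum(1 for a, g in pairs if a == g)
    per_class = {}
    for cls in (RELEVANT, IRRELEVANT):
        in_cls = [(a, g) for a, g in pairs if g == cls]
        per_class[cls] = (
            100.0 * sum(1 for a, g in in_cls if a == g) / len(in_cls) if in_cls else 0.0
        )
    return AgreementReport(
        n_agree=n_agree,
        n_total=len(pairs),
        pct_overall=100.0 * n_agree / len(pairs),
        pct_relevant=per_class[RELEVANT],
        pct_irrelevant=per_class[IRRELEVANT],
    )


def format_report(report: MetricsReport, cm: ConfusionMatrix | None = None) -> str:
    """Human-readable per-class metrics table."""
    rounded = report.rounded()
    lines = [
        f"{'Class':>5}  {'Precision':>9}  {'Recall':>6}  {'F1-score':>8}  {'Support':>7}",
    ]
    for cls in (RELEVANT, IRRELEVANT):
        m = rounded[cls]
        lines.append(
            f"{cls:>5}  {m['precision']:>9.2f}  {m['recall']:>6.2f}"
            f"  {m['f1']:>8.2f}  {m['support']:>7d}"
        )
    lines.append(f"Accuracy: {rounded['accuracy']:.2f}")
    if cm is not None:
        lines.append(f"Confusion: tp={cm.tp} fp={cm.fp} fn={cm.fn} tn={cm.tn}")
    return "\n".join(lines)
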