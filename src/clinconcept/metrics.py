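"""Span-level evaluation: precision / recall / F1, macro averages, sensitivity.

Definitions (all counts over concept spans):

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F1 = 2 * P * R / (P + R)          sensitivity = TP / (TP + FN)

Macro averages over the N classes use per-class true positives TP_i, total
inferred labels TI_i (predictions) and ground-truth totals TT_i:

    fP = (1/N) sum_i TP_i / TI_i      fR = (1/N) sum_i TP_i / TT_i
    fF = 2 * fP * fR / (fP + fR)

Matching between predictions and gold is one-to-one and greedy left-to-right,
either ``exact`` (identical span and category) or ``overlap`` (same line,
intersecting token ranges, same category). Rates are reported in [0, 1];
``as_percent`` renders them as half-up 2-decimal percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from .types import ConceptAnnotation, GoldAnnotation

logger = logging.getLogger(__name__)

CATEGORIES = ("problem", "treatment", "test")


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero with no convention to fall back on."""


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P, R, F1 from counts; zero denominators resolve to 0 by convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError(f"counts must be non-negative, got {(tp, fp, fn)}")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def sensitivity(tp: int, fn: int) -> float:
    """TP / (TP + FN); undefined when both counts are zero."""
    if tp < 0 or fn < 0:
        raise ValueError(f"counts must be non-negative, got {(tp, fn)}")
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined for tp + fn == 0")
    return tp / (tp + fn)


def as_percent(rate: float, decimals: int = 2) -> float:
    """Render a [0,1] rate as a percentage, rounded half-up."""
    quant = Decimal(10) ** -decimals
    return float(Decimal(rate * 100).quantize(quant, rounding=ROUND_HALF_UP))


def macro_average(per_class_counts: dict[str, tuple[int, int, int]],
                  n_classes: int | None = None) -> tuple[float, float, float]:
    """(fP, fR, fF) from per-class (TP, TI, TT) counts.

    Classes with TI = 0 (nothing inferred) contribute 0 to fP; likewise
    TT = 0 contributes 0 to fR. Both cases are logged.
    """
    n = n_classes if n_classes is not None else len(per_class_counts)
    if n < 1:
        raise ValueError("the number of classes must be >= 1")
    fp_sum = fr_sum = 0.0
    for cls, (tp, ti, tt) in per_class_counts.items():
        if min(tp, ti, tt) < 0:
            raise ValueError(f"counts must be non-negative for class {cls!r}")
        if ti:
            fp_sum += tp / ti
        else:
            logger.info("class %r has no inferred labels; contributes 0 to fP", cls)
        if tt:
            fr_sum += tp / tt
        else:
            logger.info("class %r has no ground-truth labels; contributes 0 to fR", cls)
    f_precision = fp_sum / n
    f_recall = fr_sum / n
    return f_precision, f_recall, f1_score(f_precision, f_recall)


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return precision_recall_f1(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return precision_recall_f1(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return precision_recall_f1(self.tp, self.fp, self.fn)[2]


@dataclass
class MetricsReport:
    """Evaluation outcome: overall and per-class counts and rates."""

    match_mode: str
    overall: ClassCounts
    per_class: dict[str, ClassCounts]
    macro_precision: float = 0.0
    macro_recall: float = 0.0
    macro_f1: float = 0.0
    n_pred: int = 0
    n_gold: int = 0

    def to_dict(self) -> dict:
        def rates(c: ClassCounts) -> dict:
            p, r, f = precision_recall_f1(c.tp, c.fp, c.fn)
            return {"tp": c.tp, "fp": c.fp, "fn": c.fn,
                    "precision": as_percent(p), "recall": as_percent(r),
                    "f1": as_percent(f)}

        return {
            "match_mode": self.match_mode,
            "n_pred": self.n_pred,
            "n_gold": self.n_gold,
            "overall": rates(self.overall),
            "per_class": {cls: rates(c) for cls, c in self.per_class.items()},
            "macro": {"precision": as_percent(self.macro_precision),
                      "recall": as_percent(self.macro_recall),
                      "f1": as_percent(self.macro_f1)},
        }


def _span_key(ann) -> tuple:
    return (ann.doc_id, *ann.location)


def _matches(pred, gold, mode: str) -> bool:
    if pred.doc_id != gold.doc_id or pred.category != gold.category:
        return False
    if mode == "exact":
        return pred.location == gold.location
    pl, ps, pe = pred.location
    gl, gs, ge = gold.location
    return pl == gl and ps <= ge and gs <= pe


def evaluate_annotations(pred: Sequence[ConceptAnnotation],
                         gold: Sequence[GoldAnnotation],
                         match_mode: str = "exact") -> MetricsReport:
    """Score predictions against gold spans with greedy one-to-one matching."""
    if match_mode not in ("exact", "overlap"):
        raise ValueError(f"match_mode must be 'exact' or 'overlap', got {match_mode!r}")
    pred_sorted = sorted(pred, key=_span_key)
    gold_sorted = sorted(gold, key=_span_key)

    per_class = {cls: ClassCounts() for cls in CATEGORIES}
    unmatched_gold = list(gold_sorted)
    for p in pred_sorted:
        hit = next((g for g in unmatched_gold if _matches(p, g, match_mode)), None)
        if hit is not None:
            unmatched_gold.remove(hit)
            per_class[p.category].tp += 1
        else:
            per_class[p.category].fp += 1
    for g in unmatched_gold:
        per_class[g.category].fn += 1

    overall = ClassCounts(
        tp=sum(c.tp for c in per_class.values()),
        fp=sum(c.fp for c in per_class.values()),
        fn=sum(c.fn for c in per_class.values()))
    macro_counts = {
        cls: (c.tp, c.tp + c.fp, c.tp + c.fn) for cls, c in per_class.items()}
    f_p, f_r, f_f = macro_average(macro_counts, len(CATEGORIES))
    return MetricsReport(match_mode=match_mode, overall=overall,
                         per_class=per_class, macro_precision=f_p,
                         macro_recall=f_r, macro_f1=f_f,
                         n_pred=len(pred_sorted), n_gold=len(gold_sorted))


def boundary_sensitivity(detected_spans: Sequence[tuple],
                         gold: Sequence[GoldAnnotation]) -> float:
    """Fraction of gold concept spans surviving boundary detection.

    ``detected_spans`` are (doc_id, line, first_token, last_token) tuples of
    retained candidate phrases; a gold span counts as detected when some
    retained candidate covers exactly its span.
    """
    detected = set(detected_spans)
    tp = sum(1 for g in gold if (g.doc_id, *g.location) in detected)
    fn = len(gold) - tp
    return sensitivity(tp, fn)
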