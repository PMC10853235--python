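"""Truth-set matching and precision/sensitivity/F-score computation.

A predicted call is a true positive when its breakpoint falls inside the
reference insertion's matching window: ±``tsd_pad`` bp around the target
site duplication (TSD) when the TSD is resolved, otherwise
±``fallback_pad`` bp around the reference breakpoint.  Both windows are
closed.  True positives are counted at the prediction level and false
negatives at the reference level, so a reference absorbed by several
nearby predictions contributes all of them to precision's numerator but
is detected only once for sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .model import CallSet, MEICall, MEIClass, ReferenceMEI

#: Marker for a metric whose denominator is empty (e.g. precision with
#: zero predictions).
UNDEFINED = float("nan")


def match_window(ref: ReferenceMEI, tsd_pad: int = 10, fallback_pad: int = 50) -> tuple[int, int]:
    """Closed matching window [low, high] for one reference insertion."""
    if ref.has_tsd:
        return ref.tsd_start - tsd_pad, ref.tsd_end + tsd_pad
    return ref.breakpoint - fallback_pad, ref.breakpoint + fallback_pad


def _class_compatible(pred: MEIClass, ref: MEIClass) -> bool:
    return pred is MEIClass.UNKNOWN or pred is ref


@dataclass
class MatchResult:
    """Outcome of matching a prediction set against a reference set."""

    n_predictions: int
    n_references: int
    pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tp_predictions(self) -> int:
        return len(self.pairs)

    @property
    def detected_references(self) -> int:
        return len({j for _, j in self.pairs})

    @property
    def fp(self) -> int:
        return self.n_predictions - self.tp_predictions

    @property
    def fn(self) -> int:
        return self.n_references - self.detected_references


def match_calls(
    predictions: CallSet | Sequence[MEICall],
    references: Sequence[ReferenceMEI],
    require_class: bool = True,
    tsd_pad: int = 10,
    fallback_pad: int = 50,
) -> MatchResult:
    """Assign each prediction to at most one reference insertion.

    Each prediction is matched to the eligible reference (window
    containing it, compatible chromosome and — with ``require_class`` —
    element class) whose breakpoint is nearest; ties go to the lower
    reference coordinate.  A reference may absorb several predictions.
    """
    preds = list(predictions)
    # interval index over reference windows, per chromosome
    trees: dict[str, IntervalTree] = {}
    for j, ref in enumerate(references):
        low, high = match_window(ref, tsd_pad, fallback_pad)
        trees.setdefault(ref.norm_chrom, IntervalTree()).addi(low, high + 1, j)

    pairs: list[tuple[int, int]] = []
    for i, call in enumerate(preds):
        tree = trees.get(call.norm_chrom)
        if tree is None:
            continue
        best: Optional[int] = None
        best_key: Optional[tuple[int, int, int]] = None
        for iv in tree.at(call.breakpoint):
            j = iv.data
            ref = references[j]
            if require_class and not _class_compatible(call.mei_class, ref.mei_class):
                continue
            # ties: nearest breakpoint, then lower coordinate, then input order
            key = (abs(call.breakpoint - ref.breakpoint), ref.breakpoint, j)
            if best_key is None or key < best_key:
                best, best_key = j, key
        if best is not None:
            pairs.append((i, best))
    return MatchResult(n_predictions=len(preds), n_references=len(references), pairs=pairs)


def f_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity; 0 on an empty or NaN input."""
    if math.isnan(precision) or math.isnan(sensitivity):
        return 0.0
    denom = precision + sensitivity
    return 2 * precision * sensitivity / denom if denom > 0 else 0.0


@dataclass
class MetricSet:
    precision: float
    sensitivity: float
    f_score: float
    per_class: dict[MEIClass, "MetricSet"] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"precision": self.precision, "sensitivity": self.sensitivity,
             "f_score": self.f_score}
        if self.per_class:
            d["per_class"] = {k.value: v.as_dict() for k, v in self.per_class.items()}
        return d


def _metrics_from_counts(tp_pred: int, fp: int, detected: int, fn: int) -> MetricSet:
    precision = tp_pred / (tp_pred + fp) if (tp_pred + fp) > 0 else UNDEFINED
    sensitivity = detected / (detected + fn) if (detected + fn) > 0 else UNDEFINED
    return MetricSet(precision, sensitivity, f_score(precision, sensitivity))


def compute_metrics(
    result: MatchResult,
    predictions: CallSet | Sequence[MEICall] | None = None,
    references: Sequence[ReferenceMEI] | None = None,
) -> MetricSet:
    """Precision, sensitivity and F-score from a match result.

    When the prediction and reference collections are supplied, per-class
    metrics are computed on the class-restricted subsets: a class's
    precision uses predictions of that class (unknown-class predictions
    count only when matched to a reference of the class), its sensitivity
    uses references of that class.
    """
    overall = _metrics_from_counts(
        result.tp_predictions, result.fp, result.detected_references, result.fn)
    if predictions is None or references is None:
        return overall

    preds = list(predictions)
    matched_ref = {i: j for i, j in result.pairs}
    for cls in (MEIClass.ALU, MEIClass.L1, MEIClass.SVA):
        tp = fp = 0
        for i, call in enumerate(preds):
            j = matched_ref.get(i)
            if j is not None and references[j].mei_class is cls:
                tp += 1
            elif j is None and call.mei_class is cls:
                fp += 1
        refs_cls = [j for j, r in enumerate(references) if r.mei_class is cls]
        detected = len({j for _, j in result.pairs if j in set(refs_cls)})
        fn = len(refs_cls) - detected
        if tp + fp + fn > 0:
            overall.per_class[cls] = _metrics_from_counts(tp, fp, detected, fn)
    return overall


def benchmark(
    predictions: CallSet | Sequence[MEICall],
    references: Sequence[ReferenceMEI],
    require_class: bool = True,
    tsd_pad: int = 10,
    fallback_pad: int = 50,
) -> MetricSet:
    """Convenience wrapper: match then compute overall and per-class metrics."""
    res = match_calls(predictions, references, require_class, tsd_pad, fallback_pad)
    return compute_metrics(res, predictions, references)


def recall_against_known_sites(
    predictions: CallSet | Sequence[MEICall],
    known_sites: Sequence[ReferenceMEI],
    require_class: bool = True,
) -> float:
    """Fraction of a known-polymorphism subset detected by the predictions."""
    if not known_sites:
        return UNDEFINED
    res = match_calls(predictions, known_sites, require_class)
    return res.detected_references / len(known_sites)
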