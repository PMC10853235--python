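"""Read-support filtering: the fixed "common" thresholds and an
F-score-optimised grid search.

The common strategy keeps calls with at least five supporting reads
(SR + DP) of which at least two are split reads for exome data, and at
least ten supporting reads with two split reads for genome data.  The
optimised strategy evaluates a grid of threshold combinations on a
training benchmark and selects the one with the highest F-score.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .benchmark import MetricSet, benchmark
from .io import SUPPORT_UNKNOWN_FLAG
from .model import Assay, CallSet, MEICall, ReferenceMEI


@dataclass(frozen=True)
class FilterSpec:
    """Thresholds a call must meet to be retained (all inclusive)."""

    min_total_support: int = 0
    min_split_reads: int = 0
    min_quality: Optional[float] = None
    drop_flags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.min_total_support < 0 or self.min_split_reads < 0:
            raise ValueError("thresholds must be non-negative")
        object.__setattr__(self, "drop_flags", frozenset(self.drop_flags))

    def passes(self, call: MEICall, exempt_unknown_support: bool = False) -> bool:
        if call.flags & self.drop_flags:
            return False
        if self.min_quality is not None and call.quality is not None \
                and call.quality < self.min_quality:
            return False
        if exempt_unknown_support and SUPPORT_UNKNOWN_FLAG in call.flags:
            return True
        return (call.total_support >= self.min_total_support
                and call.split_reads >= self.min_split_reads)

    def to_json(self) -> str:
        d = asdict(self)
        d["drop_flags"] = sorted(self.drop_flags)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "FilterSpec":
        d = json.loads(text)
        d["drop_flags"] = frozenset(d.get("drop_flags", []))
        return cls(**d)


def common_filter_spec(assay: Assay | str) -> FilterSpec:
    """The assay-specific fixed filter: ES -> (5 reads, 2 SR); GS -> (10, 2)."""
    assay = Assay(assay) if not isinstance(assay, Assay) else assay
    if assay is Assay.ES:
        return FilterSpec(min_total_support=5, min_split_reads=2)
    return FilterSpec(min_total_support=10, min_split_reads=2)


def apply_filter(
    callset: CallSet,
    spec: FilterSpec,
    exempt_unknown_support: bool = False,
) -> CallSet:
    """Retain calls passing every threshold; order preserved, idempotent.

    ``exempt_unknown_support`` lets calls from formats that report no
    read support at all bypass the SR/total thresholds (they are
    otherwise treated as zero support and removed).
    """
    return callset.subset(c for c in callset if spec.passes(c, exempt_unknown_support))


def default_grid(callset: CallSet | None = None) -> list[FilterSpec]:
    """Generic threshold grid: total support x split reads x quality.

    Quality takes two values, no threshold and the median of the observed
    qualities (skipped when the data carries no quality scores).
    """
    quals = [c.quality for c in callset if c.quality is not None] if callset else []
    quality_levels: list[Optional[float]] = [None]
    if quals:
        quality_levels.append(statistics.median(quals))
    return [
        FilterSpec(min_total_support=t, min_split_reads=s, min_quality=q)
        for t in (2, 3, 5, 8, 10)
        for s in (0, 1, 2, 4)
        for q in quality_levels
    ]


@dataclass
class GridSearchResult:
    best_spec: FilterSpec
    best_f: float
    table: list[tuple[FilterSpec, MetricSet]] = field(default_factory=list)


def _argmax_key(spec: FilterSpec, metrics: MetricSet) -> tuple:
    # maximise F, then precision; prefer the laxer spec on exact ties
    prec = metrics.precision if metrics.precision == metrics.precision else -1.0
    return (metrics.f_score, prec, -spec.min_total_support, -spec.min_split_reads)


def optimize_filter(
    train_calls: CallSet,
    train_truth: Sequence[ReferenceMEI],
    grid: Sequence[FilterSpec] | None = None,
    require_class: bool = True,
) -> GridSearchResult:
    """Grid-search filter thresholds for maximal F-score on a training set.

    Every grid point is evaluated by filtering, matching against the
    truth set and computing metrics; the argmax by F-score is returned
    (ties broken by higher precision, then lower thresholds).
    """
    grid = list(grid) if grid is not None else default_grid(train_calls)
    if not grid:
        raise ValueError("grid must be non-empty")
    table = []
    for spec in grid:
        metrics = benchmark(apply_filter(train_calls, spec), train_truth,
                            require_class=require_class)
        table.append((spec, metrics))
    best_spec, best_metrics = max(table, key=lambda t: _argmax_key(*t))
    return GridSearchResult(best_spec=best_spec, best_f=best_metrics.f_score, table=table)


def evaluate_on_holdout(
    spec: FilterSpec,
    test_calls: CallSet,
    test_truth: Sequence[ReferenceMEI],
    require_class: bool = True,
) -> MetricSet:
    """Apply a trained filter spec to held-out data, with no refitting."""
    return benchmark(apply_filter(test_calls, spec), test_truth,
                     require_class=require_class)
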