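"""Diagnostic-yield statistics.

Proportions of diagnosed cases are summarised with a normal-approximation
(Wald) 95% confidence interval clipped at zero, cohort diagnosis rates
are compared with a two-sided Fisher exact test, and per-tool clinical
sensitivity is the fraction of validated disease-causing events each
tool detected.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Set

from scipy import stats as sps


@dataclass(frozen=True)
class ProportionEstimate:
    successes: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def render_percent(self, decimals: int = 3) -> str:
        """Render as e.g. ``0.048% [0.000%-0.102%]`` (half-up rounding)."""
        def pct(x: float) -> str:
            return f"{_round_half_up(x * 100, decimals):.{decimals}f}%"
        return f"{pct(self.proportion)} [{pct(self.ci_low)}–{pct(self.ci_high)}]"


def _round_half_up(x: float, decimals: int) -> float:
    factor = 10 ** decimals
    return math.floor(x * factor + 0.5) / factor


def wald_ci(successes: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """Wald (normal-approximation) binomial CI, lower bound clipped at 0.

    half-width = z * sqrt(p(1-p)/n) with p = successes/n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    p = successes / n
    z = sps.norm.ppf(0.5 + level / 2)
    hw = z * math.sqrt(p * (1 - p) / n)
    return ProportionEstimate(successes, n, p, max(0.0, p - hw), p + hw, level)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Probability-mass definition: the sum of hypergeometric probabilities
    of all tables (with the observed margins) no more likely than the
    observed one.  A degenerate margin gives p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def clinical_sensitivity(
    detections: Mapping[str, Set[str]], cases: Set[str]
) -> tuple[dict[str, float], float]:
    """Per-tool fraction of validated diagnostic cases detected.

    Concordance is the fraction of cases detected by *every* tool.
    """
    if not cases:
        raise ValueError("cases must be non-empty")
    for tool, hits in detections.items():
        extra = set(hits) - set(cases)
        if extra:
            raise ValueError(f"{tool} reports detections outside the case set: {sorted(extra)}")
    per_tool = {tool: len(hits) / len(cases) for tool, hits in detections.items()}
    shared = set(cases)
    for hits in detections.values():
        shared &= set(hits)
    return per_tool, len(shared) / len(cases)


def load_diagnostic_cases() -> dict[str, dict]:
    """The ten published validated disease-causing MEI cases.

    Returns gene -> {cohort, mei_class, tools} where ``tools`` is the set
    of callers that detected the event in the patient's exome data.
    """
    cases: dict[str, dict] = {}
    with resources.files("meibench.data").joinpath("diagnostic_cases.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cases[row["gene"]] = {
                "cohort": row["cohort"],
                "mei_class": row["mei_class"],
                "tools": set(row["tools"].split(",")),
            }
    return cases
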