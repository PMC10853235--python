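"""Merging call sets across tools and samples into unique MEI sites.

Calls are clustered per chromosome (and per element class by default)
by single linkage with a ±``tolerance`` bp rule: sorted breakpoints are
chained while consecutive gaps stay within the tolerance.  Because the
linkage is transitive, a chain of nearby calls can span more than the
tolerance end-to-end; the invariant is on consecutive gaps.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .benchmark import match_window
from .model import CallSet, MEIClass, ReferenceMEI, normalize_chrom


@dataclass
class MergedSite:
    """One unique insertion site supported by one or more calls."""

    chrom: str
    representative_breakpoint: int
    mei_class: MEIClass
    members: list[tuple[str, str, int]]  # (sample_id, tool, breakpoint)

    @property
    def supporting_tools(self) -> set[str]:
        return {tool for _, tool, _ in self.members}

    @property
    def supporting_samples(self) -> set[str]:
        return {sample for sample, _, _ in self.members}

    @property
    def norm_chrom(self) -> str:
        return normalize_chrom(self.chrom)


def _lower_median(values: list[int]) -> int:
    values = sorted(values)
    return values[(len(values) - 1) // 2]


def _consensus_class(classes: list[MEIClass]) -> MEIClass:
    counts = collections.Counter(c for c in classes if c is not MEIClass.UNKNOWN)
    if not counts:
        return MEIClass.UNKNOWN
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return MEIClass.UNKNOWN
    return top[0][0]


def merge_callsets(
    callsets: Iterable[CallSet],
    tolerance: int = 50,
    class_aware: bool = True,
) -> list[MergedSite]:
    """Single-linkage merge of calls into unique sites.

    With ``class_aware`` (default) calls of different element classes
    never merge, so an Alu and an L1 at the same locus stay distinct;
    unknown-class calls cluster separately.  Output is sorted by
    (chromosome, representative breakpoint) and is invariant to the
    order of the input call sets.
    """
    groups: dict[tuple, list] = collections.defaultdict(list)
    for cs in callsets:
        for c in cs:
            key = (c.norm_chrom, c.mei_class) if class_aware else (c.norm_chrom,)
            groups[key].append(c)

    sites: list[MergedSite] = []
    for key, calls in groups.items():
        calls.sort(key=lambda c: (c.breakpoint, c.sample_id, c.tool))
        cluster: list = []
        for c in calls:
            if cluster and c.breakpoint - cluster[-1].breakpoint > tolerance:
                sites.append(_make_site(cluster))
                cluster = []
            cluster.append(c)
        if cluster:
            sites.append(_make_site(cluster))
    sites.sort(key=lambda s: (s.norm_chrom, s.representative_breakpoint,
                              s.mei_class.value))
    return sites


def _make_site(cluster) -> MergedSite:
    return MergedSite(
        chrom=cluster[0].chrom,
        representative_breakpoint=_lower_median([c.breakpoint for c in cluster]),
        mei_class=_consensus_class([c.mei_class for c in cluster]),
        members=[(c.sample_id, c.tool, c.breakpoint) for c in cluster],
    )


def concordance(
    merged: Sequence[MergedSite], tool_a: str, tool_b: str
) -> tuple[float, dict[str, int]]:
    """Jaccard-style overlap of two tools over the merged unique sites.

    Returns (both / (a-only + b-only + both), counts).  NaN when neither
    tool supports any site.
    """
    counts = {"a_only": 0, "b_only": 0, "both": 0}
    for site in merged:
        has_a = tool_a in site.supporting_tools
        has_b = tool_b in site.supporting_tools
        if has_a and has_b:
            counts["both"] += 1
        elif has_a:
            counts["a_only"] += 1
        elif has_b:
            counts["b_only"] += 1
    total = sum(counts.values())
    if total == 0:
        return float("nan"), counts
    return counts["both"] / total, counts


def combined_detection_rate(
    merged_predictions: Sequence[MergedSite],
    truth: Sequence[ReferenceMEI],
    tsd_pad: int = 10,
    fallback_pad: int = 50,
) -> tuple[int, int, float]:
    """Fraction of truth insertions hit by any merged site.

    A truth entry is detected when the representative breakpoint or any
    member breakpoint of any site on its chromosome falls inside its
    matching window.
    """
    if not truth:
        raise ValueError("truth set must be non-empty")
    by_chrom: dict[str, list[int]] = collections.defaultdict(list)
    for site in merged_predictions:
        by_chrom[site.norm_chrom].append(site.representative_breakpoint)
        for _, _, bp in site.members:
            by_chrom[site.norm_chrom].append(bp)
    for bps in by_chrom.values():
        bps.sort()

    import bisect

    detected = 0
    for ref in truth:
        low, high = match_window(ref, tsd_pad, fallback_pad)
        bps = by_chrom.get(ref.norm_chrom, [])
        i = bisect.bisect_left(bps, low)
        if i < len(bps) and bps[i] <= high:
            detected += 1
    return detected, len(truth), detected / len(truth)


def write_sites_tsv(sites: Sequence[MergedSite], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["chrom", "representative_breakpoint", "mei_class",
                         "n_members", "supporting_tools", "supporting_samples",
                         "members"])
        for s in sites:
            writer.writerow([
                s.chrom, s.representative_breakpoint, s.mei_class.value,
                len(s.members),
                ",".join(sorted(s.supporting_tools)),
                ",".join(sorted(s.supporting_samples)),
                ";".join(f"{smp}|{tool}|{bp}" for smp, tool, bp in s.members),
            ])
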