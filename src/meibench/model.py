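"""Core data model for mobile element insertion (MEI) call sets.

An MEI call is one predicted non-reference retrotransposon insertion
(Alu, L1 or SVA) in one sample, reported by one detection tool.  All
breakpoints are stored as 1-based single positions regardless of the
input format; BED-style half-open intervals are converted on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree


class MEIClass(str, enum.Enum):
    """Retrotransposon element class."""

    ALU = "Alu"
    L1 = "L1"
    SVA = "SVA"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, label: str) -> "MEIClass":
        """Map a free-text class label onto the enum.

        Recognises common aliases used by callers (``ALU``, ``LINE1``,
        ``L1HS``, ``SVA_E`` ...); anything unrecognised maps to
        :attr:`UNKNOWN`.
        """
        norm = label.strip().upper()
        if norm in {"ALU", "ALUY", "ALUYA5", "ALUYB8", "SINE/ALU"}:
            return cls.ALU
        if norm in {"L1", "LINE1", "LINE/L1", "L1HS", "LINE-1"}:
            return cls.L1
        if norm.startswith("SVA"):
            return cls.SVA
        return cls.UNKNOWN


class Strand(str, enum.Enum):
    FORWARD = "+"
    REVERSE = "-"
    UNKNOWN = "."

    @classmethod
    def parse(cls, label: str) -> "Strand":
        mapping = {"+": cls.FORWARD, "-": cls.REVERSE, "forward": cls.FORWARD,
                   "reverse": cls.REVERSE}
        return mapping.get(label.strip().lower() if label else ".", cls.UNKNOWN)


class Assay(str, enum.Enum):
    """Sequencing assay: exome (ES) or genome (GS)."""

    ES = "ES"
    GS = "GS"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so GRCh37 dialects compare equal."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class MEICall:
    """One predicted insertion event.

    ``split_reads`` (SR) counts junction-spanning clipped/split reads and
    ``discordant_pairs`` (DP) counts read pairs with one mate in the
    inserted element; ``total_support`` is their sum and is the quantity
    read-support filters act on.
    """

    sample_id: str
    chrom: str
    breakpoint: int
    mei_class: MEIClass = MEIClass.UNKNOWN
    strand: Strand = Strand.UNKNOWN
    split_reads: int = 0
    discordant_pairs: int = 0
    total_support: Optional[int] = None
    quality: Optional[float] = None
    tool: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.breakpoint < 1:
            raise ValueError(f"breakpoint must be >= 1, got {self.breakpoint}")
        if self.split_reads < 0 or self.discordant_pairs < 0:
            raise ValueError("read support counts must be non-negative")
        if self.total_support is None:
            self.total_support = self.split_reads + self.discordant_pairs
        self.flags = frozenset(self.flags)

    @property
    def norm_chrom(self) -> str:
        return normalize_chrom(self.chrom)


@dataclass(frozen=True)
class ReferenceMEI:
    """One truth-set insertion, optionally with its target site duplication.

    The TSD interval, when resolved (typically from long-read data),
    localises the insertion more precisely than the single breakpoint and
    drives the narrow matching window.
    """

    chrom: str
    breakpoint: int
    mei_class: MEIClass = MEIClass.ALU
    tsd_start: Optional[int] = None
    tsd_end: Optional[int] = None

    def __post_init__(self) -> None:
        if (self.tsd_start is None) != (self.tsd_end is None):
            raise ValueError("tsd_start and tsd_end must both be set or both absent")
        if self.tsd_start is not None:
            if self.tsd_start > self.tsd_end:
                raise ValueError("tsd_start must be <= tsd_end")
            if not (self.tsd_start <= self.breakpoint <= self.tsd_end):
                raise ValueError("breakpoint must lie within the TSD interval")

    @property
    def has_tsd(self) -> bool:
        return self.tsd_start is not None

    @property
    def norm_chrom(self) -> str:
        return normalize_chrom(self.chrom)


@dataclass
class CallSet:
    """An ordered collection of MEI calls with provenance."""

    calls: list[MEICall] = field(default_factory=list)
    assay: Assay = Assay.ES
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[MEICall]:
        return iter(self.calls)

    def __getitem__(self, i):
        return self.calls[i]

    def subset(self, keep: Iterable[MEICall]) -> "CallSet":
        return replace(self, calls=list(keep))


class TargetRegionSet:
    """Exome capture / exon intervals queryable with a symmetric pad.

    Intervals are stored half-open 0-based as in their BED source; point
    queries test 1-based breakpoints against each interval expanded by
    ``window_bp`` on both sides (closed bounds).
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]], window_bp: int = 50):
        self.window_bp = int(window_bp)
        self.intervals: list[tuple[str, int, int]] = []
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (start >= end)")
            self.intervals.append((chrom, start, end))
            tree = self._trees.setdefault(normalize_chrom(chrom), IntervalTree())
            # 1-based closed query range [start+1-w, end+w] -> half-open end+w+1
            tree.addi(start + 1 - self.window_bp, end + self.window_bp + 1)
        if not self.intervals:
            raise ValueError("TargetRegionSet requires at least one interval")

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, breakpoint: int) -> bool:
        """True when a 1-based breakpoint falls in any padded interval."""
        tree = self._trees.get(normalize_chrom(chrom))
        return bool(tree is not None and tree.overlaps(breakpoint))
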