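"""Readers and writers for MEI call sets and the auxiliary tables.

Three call-set dialects are supported, mirroring the heterogeneous
outputs of MEI callers: VCF (one insertion record per line, class from
the symbolic ALT or an INFO key), BED (4+ columns; interval records get
the midpoint as breakpoint), and a generic TSV with a configurable
column map.  All readers normalise to 1-based single breakpoints.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Optional, Sequence

import pysam

from .model import (
    Assay,
    CallSet,
    MEICall,
    MEIClass,
    ReferenceMEI,
    Strand,
    TargetRegionSet,
)

logger = logging.getLogger(__name__)

#: Flag a reader attaches when the source format carries no read-support
#: information at all; filters can be told to exempt such calls.
SUPPORT_UNKNOWN_FLAG = "support_unknown"

TSV_COLUMNS = [
    "sample_id", "chrom", "breakpoint", "mei_class", "strand",
    "split_reads", "discordant_pairs", "total_support", "quality",
    "tool", "flags",
]


class CallsetParseError(ValueError):
    """Raised for an unparseable record, naming the offending line."""


def read_callset(
    path: str | Path,
    format: str,
    sample_id: str = "",
    tool: str = "",
    assay: Assay | str = Assay.ES,
    *,
    class_info_key: str = "MEICLASS",
    sr_info_key: str = "SR",
    dp_info_key: str = "DP",
    one_based: bool = True,
) -> CallSet:
    """Read a call set from ``path`` in the named dialect.

    Parameters
    ----------
    format
        One of ``vcf``, ``bed``, ``tsv``.
    one_based
        For the TSV dialect only: whether the breakpoint column is
        1-based (default) or 0-based.
    """
    assay = Assay(assay) if not isinstance(assay, Assay) else assay
    path = Path(path)
    if format == "vcf":
        calls = _read_vcf(path, sample_id, tool, class_info_key, sr_info_key, dp_info_key)
    elif format == "bed":
        calls = _read_bed(path, sample_id, tool)
    elif format == "tsv":
        calls = _read_tsv(path, sample_id, tool, one_based)
    else:
        raise ValueError(f"unknown call-set format: {format!r}")
    return CallSet(calls=calls, assay=assay, provenance=str(path))


def _class_from_alt(alt: str) -> Optional[MEIClass]:
    # symbolic ALT like <INS:ME:ALU>
    if alt and alt.startswith("<") and "ME" in alt:
        return MEIClass.parse(alt.strip("<>").split(":")[-1])
    return None


def _parse_class(label: str, where: str) -> MEIClass:
    cls = MEIClass.parse(label)
    if cls is MEIClass.UNKNOWN and label.strip().lower() not in {"", "unknown", "."}:
        logger.warning("unknown MEI class label %r at %s; mapped to 'unknown'", label, where)
    return cls


def _info_int(rec, key: str) -> Optional[int]:
    val = rec.info.get(key)
    if val is None:
        return None
    if isinstance(val, (tuple, list)):
        val = val[0]
    return int(val)


def _read_vcf(path, sample_id, tool, class_key, sr_key, dp_key) -> list[MEICall]:
    calls: list[MEICall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            mei_class = None
            if rec.alts:
                mei_class = _class_from_alt(rec.alts[0])
            if mei_class is None:
                label = rec.info.get(class_key, "")
                if isinstance(label, (tuple, list)):
                    label = label[0]
                mei_class = _parse_class(str(label), f"{path}:{rec.pos}")
            sr = _info_int(rec, sr_key)
            dp = _info_int(rec, dp_key)
            flags = frozenset(f for f in rec.filter.keys() if f not in ("PASS", "."))
            if sr is None and dp is None:
                flags |= {SUPPORT_UNKNOWN_FLAG}
            strand = Strand.parse(str(rec.info.get("STRAND", "."))) \
                if "STRAND" in rec.info else Strand.UNKNOWN
            calls.append(MEICall(
                sample_id=sample_id, chrom=rec.chrom, breakpoint=rec.pos,
                mei_class=mei_class, strand=strand,
                split_reads=sr or 0, discordant_pairs=dp or 0,
                quality=None if rec.qual is None else float(rec.qual),
                tool=tool, flags=flags,
            ))
    return calls


def _read_bed(path, sample_id, tool) -> list[MEICall]:
    calls: list[MEICall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                if start >= end:
                    raise ValueError("start >= end")
            except (IndexError, ValueError) as exc:
                raise CallsetParseError(f"{path} line {lineno}: {exc}") from exc
            # single-base record -> start+1; interval record -> lower-median midpoint
            breakpoint = (start + end + 1) // 2
            mei_class = MEIClass.UNKNOWN
            if len(fields) > 3 and fields[3] not in (".", ""):
                mei_class = _parse_class(fields[3], f"{path} line {lineno}")
            quality = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                quality = float(fields[4])
            strand = Strand.parse(fields[5]) if len(fields) > 5 else Strand.UNKNOWN
            calls.append(MEICall(
                sample_id=sample_id, chrom=chrom, breakpoint=breakpoint,
                mei_class=mei_class, strand=strand, quality=quality,
                tool=tool, flags=frozenset({SUPPORT_UNKNOWN_FLAG}),
            ))
    return calls


def _read_tsv(path, sample_id, tool, one_based) -> list[MEICall]:
    calls: list[MEICall] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            try:
                bp = int(row["breakpoint"])
                if not one_based:
                    bp += 1
                quality = row.get("quality") or None
                flags = frozenset(f for f in (row.get("flags") or "").split(",") if f)
                calls.append(MEICall(
                    sample_id=row.get("sample_id") or sample_id,
                    chrom=row["chrom"],
                    breakpoint=bp,
                    mei_class=_parse_class(row.get("mei_class", ""), f"{path} line {lineno}"),
                    strand=Strand.parse(row.get("strand", ".")),
                    split_reads=int(row.get("split_reads") or 0),
                    discordant_pairs=int(row.get("discordant_pairs") or 0),
                    quality=None if quality is None else float(quality),
                    tool=row.get("tool") or tool,
                    flags=flags,
                ))
            except (KeyError, ValueError) as exc:
                raise CallsetParseError(f"{path} line {lineno}: {exc}") from exc
    return calls


def write_callset(callset: CallSet, path: str | Path, format: str = "tsv") -> None:
    """Write a call set as TSV (full fidelity) or minimal VCF."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(TSV_COLUMNS)
            for c in callset:
                writer.writerow([
                    c.sample_id, c.chrom, c.breakpoint, c.mei_class.value,
                    {"+": "forward", "-": "reverse", ".": "unknown"}[c.strand.value],
                    c.split_reads, c.discordant_pairs, c.total_support,
                    "" if c.quality is None else c.quality,
                    c.tool, ",".join(sorted(c.flags)),
                ])
    elif format == "vcf":
        _write_vcf(callset, path)
    else:
        raise ValueError(f"unknown output format: {format!r}")


def _write_vcf(callset: CallSet, path: Path) -> None:
    filters = sorted({f for c in callset for f in c.flags} - {SUPPORT_UNKNOWN_FLAG})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MEICLASS,Number=1,Type=String,Description="Mobile element class">\n')
        fh.write('##INFO=<ID=SR,Number=1,Type=Integer,Description="Split/clipped reads">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Discordant pairs">\n')
        fh.write('##INFO=<ID=STRAND,Number=1,Type=String,Description="Insertion strand">\n')
        for f in filters:
            fh.write(f'##FILTER=<ID={f},Description="Caller flag">\n')
        for chrom in sorted({c.chrom for c in callset}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in callset:
            alt = {MEIClass.ALU: "<INS:ME:ALU>", MEIClass.L1: "<INS:ME:L1>",
                   MEIClass.SVA: "<INS:ME:SVA>"}.get(c.mei_class, "<INS:ME>")
            qual = "." if c.quality is None else f"{c.quality:g}"
            flt = ";".join(sorted(c.flags - {SUPPORT_UNKNOWN_FLAG})) or "PASS"
            info = (f"MEICLASS={c.mei_class.value};SR={c.split_reads};"
                    f"DP={c.discordant_pairs};STRAND={c.strand.value}")
            fh.write(f"{c.chrom}\t{c.breakpoint}\t.\tN\t{alt}\t{qual}\t{flt}\t{info}\n")


def restrict_to_target_regions(callset: CallSet, targets: TargetRegionSet) -> CallSet:
    """Keep calls whose breakpoint falls within the padded target regions.

    The pad is ``targets.window_bp`` on each side of every interval,
    closed at both boundaries.  Order is preserved; idempotent.
    """
    return callset.subset(c for c in callset if targets.contains(c.chrom, c.breakpoint))


# ---------------------------------------------------------------------------
# auxiliary tables


def read_targets_bed(path: str | Path, window_bp: int = 50) -> TargetRegionSet:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return TargetRegionSet(intervals, window_bp=window_bp)


def read_reference_meis(path: str | Path) -> list[ReferenceMEI]:
    """Read a truth / known-site table.

    Tab-delimited with header: chrom, breakpoint, mei_class and optional
    tsd_start / tsd_end columns (blank when the TSD is unresolved).
    """
    refs: list[ReferenceMEI] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            try:
                tsd_start = row.get("tsd_start") or None
                tsd_end = row.get("tsd_end") or None
                refs.append(ReferenceMEI(
                    chrom=row["chrom"],
                    breakpoint=int(row["breakpoint"]),
                    mei_class=_parse_class(row.get("mei_class", "Alu"), f"{path} line {lineno}"),
                    tsd_start=None if tsd_start is None else int(tsd_start),
                    tsd_end=None if tsd_end is None else int(tsd_end),
                ))
            except (KeyError, ValueError) as exc:
                raise CallsetParseError(f"{path} line {lineno}: {exc}") from exc
    return refs


def write_reference_meis(refs: Sequence[ReferenceMEI], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["chrom", "breakpoint", "mei_class", "tsd_start", "tsd_end"])
        for r in refs:
            writer.writerow([
                r.chrom, r.breakpoint, r.mei_class.value,
                "" if r.tsd_start is None else r.tsd_start,
                "" if r.tsd_end is None else r.tsd_end,
            ])
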