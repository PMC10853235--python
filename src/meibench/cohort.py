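"""Rare-disease cohort prioritisation of merged MEI sites.

The diagnostic cascade, applied in order to the unique sites of a
cohort:

1. restrict to exome target regions (±50 bp of exon boundaries),
2. remove sites carried by any unaffected sample,
3. remove sites at known polymorphic insertion loci (dbRIP-style list),
4. keep only rare sites (carrier frequency strictly below a threshold,
   computed over all cohort samples before any exclusion),
5. keep only sites in a carrier's phenotype-driven gene panel,
   optionally restricted to exonic/splice-region hits.

Each stage only removes sites, so the cascade is monotone decreasing;
per-stage survivor counts are logged for audit.
"""

from __future__ import annotations

import collections
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .merging import MergedSite
from .model import MEIClass, ReferenceMEI, TargetRegionSet, normalize_chrom

logger = logging.getLogger(__name__)


@dataclass
class CohortTable:
    """Sample metadata plus the merged sites observed in the cohort."""

    samples: pd.DataFrame  # columns: sample_id, family_id, affected, panel
    sites: list[MergedSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"sample_id", "family_id", "affected", "panel"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"cohort metadata missing columns: {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in cohort metadata")
        self._affected = dict(zip(self.samples["sample_id"], self.samples["affected"]))
        self._panel = dict(zip(self.samples["sample_id"], self.samples["panel"]))
        for site in self.sites:
            unknown = site.supporting_samples - self._affected.keys()
            if unknown:
                raise ValueError(f"carriers not in cohort metadata: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_affected(self, sample_id: str) -> bool:
        try:
            return bool(self._affected[sample_id])
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in cohort metadata") from None

    def panel_of(self, sample_id: str) -> Optional[str]:
        panel = self._panel.get(sample_id)
        return None if panel in (None, "", float("nan")) or pd.isna(panel) else panel

    @classmethod
    def from_tsv(cls, path, sites: Sequence[MergedSite] = ()) -> "CohortTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str})
        df["affected"] = df["affected"].map(
            lambda v: str(v).strip().lower() in {"1", "true", "yes", "affected"})
        return cls(samples=df, sites=list(sites))


class GeneAnnotation:
    """Exon intervals per gene, with derived splice regions.

    Splice regions are the ``splice_pad`` bp flanking each exon boundary
    (default 8); deeper intronic positions get feature ``intron`` when
    they fall inside a gene's span.
    """

    def __init__(
        self,
        exons: Sequence[tuple[str, int, int, str]],  # chrom, start, end (0-based half-open), gene
        splice_pad: int = 8,
    ):
        self.splice_pad = splice_pad
        self.exons = list(exons)
        self._exon_trees: dict[str, IntervalTree] = {}
        self._splice_trees: dict[str, IntervalTree] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        gene_span: dict[tuple[str, str], list[int]] = {}
        for chrom, start, end, gene in self.exons:
            if start >= end:
                raise ValueError(f"invalid exon {chrom}:{start}-{end}")
            nchrom = normalize_chrom(chrom)
            self._exon_trees.setdefault(nchrom, IntervalTree()).addi(start + 1, end + 1, gene)
            st = self._splice_trees.setdefault(nchrom, IntervalTree())
            st.addi(start + 1 - splice_pad, start + 1, gene)
            st.addi(end + 1, end + 1 + splice_pad, gene)
            span = gene_span.setdefault((nchrom, gene), [start, end])
            span[0] = min(span[0], start)
            span[1] = max(span[1], end)
        for (nchrom, gene), (start, end) in gene_span.items():
            self._gene_trees.setdefault(nchrom, IntervalTree()).addi(start + 1, end + 1, gene)

    def genes_near(
        self, chrom: str, breakpoint: int, pad: int = 50,
        exonic_splice_only: bool = False,
    ) -> set[str]:
        """Genes whose (exonic/splice or whole-gene) footprint lies within
        ``pad`` bp of a 1-based breakpoint."""
        nchrom = normalize_chrom(chrom)
        trees = ([self._exon_trees, self._splice_trees] if exonic_splice_only
                 else [self._gene_trees])
        hits: set[str] = set()
        for td in trees:
            tree = td.get(nchrom)
            if tree is not None:
                hits |= {iv.data for iv in tree.overlap(breakpoint - pad, breakpoint + pad + 1)}
        return hits

    @classmethod
    def from_tsv(cls, path, splice_pad: int = 8) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t")
        exons = [(str(r.chrom), int(r.start), int(r.end), str(r.gene))
                 for r in df.itertuples()]
        return cls(exons, splice_pad=splice_pad)


def read_panels(path) -> dict[str, set[str]]:
    """Panel definitions: TSV with columns panel, gene."""
    df = pd.read_csv(path, sep="\t")
    panels: dict[str, set[str]] = collections.defaultdict(set)
    for r in df.itertuples():
        panels[str(r.panel)].add(str(r.gene))
    return dict(panels)


# ---------------------------------------------------------------------------
# cascade stages


def carrier_frequency(site: MergedSite, cohort: CohortTable) -> float:
    """Fraction of cohort samples carrying a call at the site."""
    if cohort.n_samples == 0:
        raise ValueError("cohort is empty")
    return len(site.supporting_samples) / cohort.n_samples


def restrict_sites_to_targets(
    sites: Sequence[MergedSite], targets: TargetRegionSet
) -> list[MergedSite]:
    return [s for s in sites if targets.contains(s.chrom, s.representative_breakpoint)]


def exclude_unaffected_carriers(
    sites: Sequence[MergedSite], cohort: CohortTable
) -> list[MergedSite]:
    """Drop any site carried by at least one unaffected sample."""
    kept = []
    for site in sites:
        statuses = [cohort.is_affected(s) for s in site.supporting_samples]
        if all(statuses):
            kept.append(site)
    return kept


def exclude_known_sites(
    sites: Sequence[MergedSite],
    known: Sequence[ReferenceMEI],
    pad: int = 50,
    class_aware: bool = True,
) -> list[MergedSite]:
    """Drop sites within ±pad of a known polymorphic insertion locus."""
    trees: dict = {}
    for ref in known:
        key = (ref.norm_chrom, ref.mei_class) if class_aware else (ref.norm_chrom,)
        trees.setdefault(key, IntervalTree()).addi(
            ref.breakpoint - pad, ref.breakpoint + pad + 1)
    kept = []
    for site in sites:
        key = (site.norm_chrom, site.mei_class) if class_aware else (site.norm_chrom,)
        tree = trees.get(key)
        if tree is None or not tree.overlaps(site.representative_breakpoint):
            kept.append(site)
    return kept


def frequency_filter(
    sites: Sequence[MergedSite], cohort: CohortTable, max_frequency: float
) -> list[MergedSite]:
    """Keep sites with carrier frequency strictly below ``max_frequency``."""
    return [s for s in sites if carrier_frequency(s, cohort) < max_frequency]


def panel_filter(
    sites: Sequence[MergedSite],
    cohort: CohortTable,
    genes: GeneAnnotation,
    panels: dict[str, set[str]],
    exonic_splice_only: bool = False,
    pad: int = 50,
) -> list[MergedSite]:
    """Keep sites hitting a gene in the panel of at least one carrier."""
    kept = []
    for site in sites:
        hit_genes = genes.genes_near(site.chrom, site.representative_breakpoint,
                                     pad=pad, exonic_splice_only=exonic_splice_only)
        if not hit_genes:
            continue
        for sample in site.supporting_samples:
            panel_name = cohort.panel_of(sample)
            if panel_name is None:
                continue
            if panel_name not in panels:
                raise KeyError(f"unknown panel {panel_name!r} for sample {sample!r}")
            if hit_genes & panels[panel_name]:
                kept.append(site)
                break
    return kept


@dataclass
class PrioritizationConfig:
    targets: Optional[TargetRegionSet] = None
    known_sites: Sequence[ReferenceMEI] = ()
    genes: Optional[GeneAnnotation] = None
    panels: dict[str, set[str]] = field(default_factory=dict)
    max_frequency: Optional[float] = 0.0003
    exonic_splice_only: bool = False
    known_pad: int = 50
    panel_pad: int = 50


@dataclass
class PrioritizationResult:
    candidates: pd.DataFrame
    sites: list[MergedSite]
    stage_log: list[tuple[str, int]]


def prioritize(cohort: CohortTable, config: PrioritizationConfig) -> PrioritizationResult:
    """Run the full diagnostic cascade and emit a candidate report.

    Stages whose inputs are not configured (no target set, empty known
    list, no frequency threshold, no gene annotation) pass sites through
    unchanged.  Candidate rows are one per (affected carrier, site),
    sorted by (sample, chromosome, position).
    """
    sites = list(cohort.sites)
    log: list[tuple[str, int]] = [("input", len(sites))]

    if config.targets is not None:
        sites = restrict_sites_to_targets(sites, config.targets)
    log.append(("target_regions", len(sites)))

    sites = exclude_unaffected_carriers(sites, cohort)
    log.append(("unaffected_excluded", len(sites)))

    if config.known_sites:
        sites = exclude_known_sites(sites, config.known_sites, pad=config.known_pad)
    log.append(("known_sites_excluded", len(sites)))

    if config.max_frequency is not None:
        sites = frequency_filter(sites, cohort, config.max_frequency)
    log.append(("frequency", len(sites)))

    if config.genes is not None:
        sites = panel_filter(sites, cohort, config.genes, config.panels,
                             exonic_splice_only=config.exonic_splice_only,
                             pad=config.panel_pad)
    log.append(("panel", len(sites)))

    for stage, n in log:
        logger.info("prioritisation stage %-20s %d sites", stage, n)

    rows = []
    for site in sites:
        freq = carrier_frequency(site, cohort)
        gene_hits = (sorted(config.genes.genes_near(
            site.chrom, site.representative_breakpoint, pad=config.panel_pad,
            exonic_splice_only=config.exonic_splice_only))
            if config.genes is not None else [])
        for sample in sorted(site.supporting_samples):
            if not cohort.is_affected(sample):
                continue
            rows.append({
                "sample_id": sample,
                "chrom": site.chrom,
                "position": site.representative_breakpoint,
                "mei_class": site.mei_class.value,
                "genes": ",".join(gene_hits),
                "n_carriers": len(site.supporting_samples),
                "carrier_frequency": freq,
                "tools": ",".join(sorted(site.supporting_tools)),
            })
    df = pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "position", "mei_class", "genes",
        "n_carriers", "carrier_frequency", "tools"])
    if len(df):
        df = df.sort_values(["sample_id", "chrom", "position"]).reset_index(drop=True)
    return PrioritizationResult(candidates=df, sites=sites, stage_log=log)
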