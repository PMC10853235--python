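"""Synthetic MEI truth sets, caller outputs and rare-disease cohorts.

The generator emulates the statistical structure the pipeline assumes
rather than reads or sequences: truth insertions with the empirical
element-class mix of exome truth sets (~88% Alu, ~9% L1, ~3% SVA) and
partially-resolved TSD intervals; per-tool call sets with class-specific
sensitivity, Gaussian breakpoint jitter, negative-binomial read support
split into SR and DP, and uniformly placed false positives; and cohorts
of affected/unaffected samples carrying common polymorphic insertions
plus rare spiked-in pathogenic events in panel-gene exons.

Every generated call is labelled with its ground truth, so the
generator's bookkeeping serves as the oracle for end-to-end tests.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, GeneAnnotation, PrioritizationConfig
from .merging import MergedSite, merge_callsets
from .model import (Assay, CallSet, MEICall, MEIClass, ReferenceMEI,
                    TargetRegionSet, normalize_chrom)

CLASSES = (MEIClass.ALU, MEIClass.L1, MEIClass.SVA)

#: Minimum spacing between placed truth sites, and the exclusion halo
#: around truth sites inside which no false positive is placed, so that
#: matching windows never overlap and generator labels stay unambiguous.
MIN_SITE_SPACING = 200
FP_EXCLUSION = 100


@dataclass(frozen=True)
class ToolProfile:
    """Behavioural parameters of one simulated caller."""

    sens_by_class: dict[MEIClass, float]
    fp_per_mb: float = 0.5
    breakpoint_sd: float = 5.0
    support_mean: float = 12.0
    support_dispersion: float = 3.0
    sr_fraction: float = 0.5
    fp_support_mean: Optional[float] = None  # defaults to support_mean / 3

    def sensitivity(self, cls: MEIClass) -> float:
        return self.sens_by_class.get(cls, 0.0)


def uniform_profile(sensitivity: float, **kw) -> ToolProfile:
    return ToolProfile(sens_by_class={c: sensitivity for c in CLASSES}, **kw)


#: Exome presets loosely shaped on the two best-performing exome callers:
#: a DP+SR caller with good poly-A-tail handling but weaker low-DP events,
#: and an SR-only caller that misses poly-A-only captures (lower SVA/L1
#: sensitivity) but reports mostly split reads.
ES_TOOL_PRESETS = {
    "toolA": ToolProfile(
        sens_by_class={MEIClass.ALU: 0.70, MEIClass.L1: 0.60, MEIClass.SVA: 0.50},
        fp_per_mb=0.5, breakpoint_sd=5.0, support_mean=12.0,
        support_dispersion=3.0, sr_fraction=0.4),
    "toolB": ToolProfile(
        sens_by_class={MEIClass.ALU: 0.65, MEIClass.L1: 0.45, MEIClass.SVA: 0.30},
        fp_per_mb=0.8, breakpoint_sd=4.0, support_mean=10.0,
        support_dispersion=3.0, sr_fraction=0.9),
}


@dataclass
class CohortConfig:
    n_samples: int = 500
    n_affected: int = 350
    n_polymorphic_sites: int = 40
    site_frequency_range: tuple[float, float] = (0.005, 0.05)
    n_pathogenic_spikes: int = 1
    n_spikes_in_unaffected: int = 0  # spikes additionally carried by an unaffected sample
    #: carrier-frequency threshold separating the generator's rare spikes
    #: from its common polymorphic band (whose nominal lower edge this is)
    rare_max_frequency: float = 0.005
    tool_profiles: dict[str, ToolProfile] = field(default_factory=lambda: {
        "toolA": ToolProfile(
            sens_by_class={c: 0.90 for c in CLASSES},
            fp_per_mb=0.0, breakpoint_sd=3.0, support_mean=12.0,
            support_dispersion=3.0, sr_fraction=0.4),
        "toolB": ToolProfile(
            sens_by_class={c: 0.85 for c in CLASSES},
            fp_per_mb=0.0, breakpoint_sd=3.0, support_mean=10.0,
            support_dispersion=3.0, sr_fraction=0.9),
    })


@dataclass
class SimConfig:
    seed: int = 0
    genome: list[tuple[str, int]] = field(default_factory=lambda: [
        ("1", 30_000_000), ("2", 20_000_000)])
    n_truth: int = 1000
    class_mix: tuple[float, float, float] = (0.88, 0.09, 0.03)
    tsd_length_range: tuple[int, int] = (5, 20)
    tsd_known_prob: float = 0.8
    per_tool: dict[str, ToolProfile] = field(
        default_factory=lambda: dict(ES_TOOL_PRESETS))
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _spaced_positions(rng, length: int, n: int, gap: int = MIN_SITE_SPACING) -> list[int]:
    """n uniform positions on [1, length] with pairwise spacing > gap."""
    span = length - (n - 1) * gap
    if n > 0 and span < n:
        raise ValueError(f"cannot place {n} sites with {gap} bp spacing on length {length}")
    if n == 0:
        return []
    base = np.sort(rng.choice(span, size=n, replace=False)) + 1
    return list(base + gap * np.arange(n))


def _draw_classes(rng, n: int, class_mix) -> list[MEIClass]:
    idx = rng.choice(3, size=n, p=list(class_mix))
    return [CLASSES[i] for i in idx]


def simulate_truth(config: SimConfig, rng=None) -> list[ReferenceMEI]:
    """Place truth insertions uniformly on the genome.

    Site counts per chromosome are multinomial in chromosome length;
    TSD intervals are attached with probability ``tsd_known_prob``.
    """
    rng = _rng(config.seed if rng is None else rng)
    lengths = np.array([l for _, l in config.genome], dtype=float)
    counts = rng.multinomial(config.n_truth, lengths / lengths.sum())
    refs: list[ReferenceMEI] = []
    for (chrom, length), n in zip(config.genome, counts):
        positions = _spaced_positions(rng, length, int(n))
        classes = _draw_classes(rng, int(n), config.class_mix)
        for pos, cls in zip(positions, classes):
            tsd_start = tsd_end = None
            if rng.random() < config.tsd_known_prob:
                lo, hi = config.tsd_length_range
                tsd_len = int(rng.integers(lo, hi + 1))
                offset = int(rng.integers(0, tsd_len))
                tsd_start = max(1, pos - offset)
                tsd_end = tsd_start + tsd_len - 1
            refs.append(ReferenceMEI(chrom=chrom, breakpoint=int(pos), mei_class=cls,
                                     tsd_start=tsd_start, tsd_end=tsd_end))
    return refs


@dataclass
class SimulatedCalls:
    """A simulated call set plus its ground-truth labels."""

    callset: CallSet
    truth_index: list[Optional[int]]  # per call: truth index, or None for FP
    emitted: list[bool]               # per truth site: was a call emitted

    @property
    def n_false_positives(self) -> int:
        return sum(1 for t in self.truth_index if t is None)


def _draw_support(rng, mean: float, dispersion: float, sr_fraction: float) -> tuple[int, int]:
    p = dispersion / (dispersion + mean)
    total = max(1, int(rng.negative_binomial(dispersion, p)))
    sr = int(rng.binomial(total, sr_fraction))
    return sr, total - sr


def simulate_tool_calls(
    truth: Sequence[ReferenceMEI],
    profile: ToolProfile,
    rng_or_seed,
    sample_id: str = "S1",
    tool: str = "tool",
    assay: Assay = Assay.ES,
    genome: Sequence[tuple[str, int]] = (),
    class_mix: tuple[float, float, float] = (0.88, 0.09, 0.03),
) -> SimulatedCalls:
    """Emit one caller's output over a truth set.

    Each truth site is detected with its class-specific sensitivity; the
    emitted breakpoint is the true one plus rounded N(0, breakpoint_sd)
    jitter (a large excursion past the matching window becomes a
    coupled FN + FP, the generator's miss mechanism).  SR/DP counts are
    negative-binomial split binomially at ``sr_fraction``.  False
    positives are Poisson at ``fp_per_mb`` per megabase, placed
    uniformly but never within ±100 bp of a truth site.
    """
    rng = _rng(rng_or_seed)
    records: list[tuple[str, int, MEIClass, int, int, Optional[int]]] = []
    emitted = []
    for j, ref in enumerate(truth):
        if rng.random() < profile.sensitivity(ref.mei_class):
            jitter = int(round(rng.normal(0.0, profile.breakpoint_sd)))
            bp = max(1, ref.breakpoint + jitter)
            sr, dp = _draw_support(rng, profile.support_mean,
                                   profile.support_dispersion, profile.sr_fraction)
            records.append((ref.chrom, bp, ref.mei_class, sr, dp, j))
            emitted.append(True)
        else:
            emitted.append(False)

    truth_by_chrom: dict[str, list[int]] = {}
    for ref in truth:
        truth_by_chrom.setdefault(ref.norm_chrom, []).append(ref.breakpoint)
    for v in truth_by_chrom.values():
        v.sort()

    fp_mean = profile.fp_support_mean or max(1.0, profile.support_mean / 3)
    for chrom, length in genome:
        n_fp = rng.poisson(profile.fp_per_mb * length / 1e6)
        placed = 0
        occupied = truth_by_chrom.get(chrom.replace("chr", ""), [])
        while placed < n_fp:
            pos = int(rng.integers(1, length + 1))
            i = bisect.bisect_left(occupied, pos - FP_EXCLUSION)
            if i < len(occupied) and occupied[i] <= pos + FP_EXCLUSION:
                continue
            cls = _draw_classes(rng, 1, class_mix)[0]
            sr, dp = _draw_support(rng, fp_mean, profile.support_dispersion,
                                   profile.sr_fraction)
            records.append((chrom, pos, cls, sr, dp, None))
            placed += 1

    records.sort(key=lambda r: (r[0], r[1], r[2].value))
    calls = [MEICall(sample_id=sample_id, chrom=c, breakpoint=bp, mei_class=cls,
                     split_reads=sr, discordant_pairs=dp, tool=tool)
             for c, bp, cls, sr, dp, _ in records]
    return SimulatedCalls(
        callset=CallSet(calls=calls, assay=assay, provenance=f"simulated:{tool}"),
        truth_index=[r[5] for r in records],
        emitted=emitted,
    )


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SpikeRecord:
    sample_id: str
    chrom: str
    breakpoint: int
    gene: str
    affected: bool
    emitted_by: set[str] = field(default_factory=set)
    also_in_unaffected: Optional[str] = None


@dataclass
class CohortSim:
    """A simulated cohort with full ground-truth bookkeeping."""

    cohort: CohortTable
    callsets: list[CallSet]
    sites: list[MergedSite]
    targets: TargetRegionSet
    genes: GeneAnnotation
    panels: dict[str, set[str]]
    known_sites: list[ReferenceMEI]      # the polymorphic loci
    spikes: list[SpikeRecord]
    polymorphic_frequencies: list[float]
    config: SimConfig

    def expected_candidate_samples(self) -> set[tuple[str, str]]:
        """(sample_id, gene) pairs the cascade should recover: spikes that
        were emitted by at least one caller and are carried only by
        affected samples."""
        return {(s.sample_id, s.gene) for s in self.spikes
                if s.emitted_by and s.affected and s.also_in_unaffected is None}

    def prioritization_config(self, exonic_splice_only: bool = False) -> PrioritizationConfig:
        return PrioritizationConfig(
            targets=self.targets,
            known_sites=self.known_sites,
            genes=self.genes,
            panels=self.panels,
            max_frequency=self.config.cohort.rare_max_frequency,
            exonic_splice_only=exonic_splice_only,
        )


def _build_gene_annotation(genome, n_genes: int = 30,
                           exons_per_gene: int = 5,
                           exon_len: int = 150,
                           intron_len: int = 2000) -> tuple[GeneAnnotation, TargetRegionSet, dict[str, set[str]]]:
    gene_span = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    exons = []
    genes_per_chrom = n_genes // len(genome) + 1
    gene_idx = 0
    for chrom, length in genome:
        stride = length // (genes_per_chrom + 1)
        for g in range(genes_per_chrom):
            if gene_idx >= n_genes:
                break
            start = (g + 1) * stride
            if start + gene_span >= length:
                break
            name = f"GENE{gene_idx:03d}"
            for e in range(exons_per_gene):
                s = start + e * (exon_len + intron_len)
                exons.append((chrom, s, s + exon_len, name))
            gene_idx += 1
    annotation = GeneAnnotation(exons)
    targets = TargetRegionSet([(c, s, e) for c, s, e, _ in exons], window_bp=50)
    names = sorted({g for _, _, _, g in exons})
    half = len(names) // 2
    panels = {"panelA": set(names[:half]), "panelB": set(names[half:])}
    return annotation, targets, panels


def simulate_cohort(config: SimConfig, rng=None) -> CohortSim:
    """Simulate a full cohort: samples, polymorphic sites, pathogenic
    spikes, per-sample caller output, and the merged site table.

    Polymorphic loci double as the known-polymorphism (dbRIP-style)
    exclusion list, mirroring how common insertions are catalogued.
    Spikes are placed centrally in exons of a gene from the carrier's
    own panel, at least 250 bp from any polymorphic locus.
    """
    cc = config.cohort
    if cc.n_affected > cc.n_samples:
        raise ValueError("n_affected exceeds n_samples")
    if cc.n_pathogenic_spikes > cc.n_affected:
        raise ValueError("more spikes than affected samples")
    rng = _rng(config.seed if rng is None else rng)

    genes, targets, panels = _build_gene_annotation(config.genome)
    panel_names = sorted(panels)

    sample_ids = [f"S{i:04d}" for i in range(cc.n_samples)]
    affected = [i < cc.n_affected for i in range(cc.n_samples)]
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "family_id": [f"F{i:04d}" for i in range(cc.n_samples)],
        "affected": affected,
        "panel": [panel_names[i % len(panel_names)] if affected[i] else ""
                  for i in range(cc.n_samples)],
    })

    # common polymorphic loci, uniformly placed; these are the known sites
    poly_cfg = replace(config, n_truth=cc.n_polymorphic_sites, tsd_known_prob=0.0)
    polymorphic = simulate_truth(poly_cfg, rng)
    freqs = list(rng.uniform(*cc.site_frequency_range, size=len(polymorphic)))
    carriers_per_site = [
        set(np.array(sample_ids)[rng.random(cc.n_samples) < f]) for f in freqs]

    poly_positions = {(p.norm_chrom, p.breakpoint) for p in polymorphic}

    # pathogenic spikes: distinct affected samples, exon of the carrier's panel
    spike_samples = rng.choice(cc.n_affected, size=cc.n_pathogenic_spikes, replace=False)
    unaffected_pool = [s for s, a in zip(sample_ids, affected) if not a]
    spikes: list[SpikeRecord] = []
    for k, si in enumerate(spike_samples):
        sample = sample_ids[int(si)]
        panel_genes = sorted(panels[meta.loc[int(si), "panel"]])
        for _ in range(1000):
            gene = panel_genes[int(rng.integers(len(panel_genes)))]
            gene_exons = [(c, s, e) for c, s, e, g in genes.exons if g == gene]
            chrom, s, e = gene_exons[int(rng.integers(len(gene_exons)))]
            pos = int(rng.integers(s + 31, e - 29))  # central placement
            near_poly = any(nc == normalize_chrom(chrom) and abs(pb - pos) <= 250
                            for nc, pb in poly_positions)
            if not near_poly:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not place spike away from polymorphic loci")
        also = None
        if k < cc.n_spikes_in_unaffected and unaffected_pool:
            also = unaffected_pool[int(rng.integers(len(unaffected_pool)))]
        spikes.append(SpikeRecord(sample_id=sample, chrom=chrom, breakpoint=pos,
                                  gene=gene, affected=True, also_in_unaffected=also))

    # per-sample truth and caller output
    callsets: list[CallSet] = []
    for i, sample in enumerate(sample_ids):
        truth: list[ReferenceMEI] = [
            p for p, carriers in zip(polymorphic, carriers_per_site)
            if sample in carriers]
        spike_refs: list[tuple[int, ReferenceMEI]] = []
        for k, sp in enumerate(spikes):
            if sp.sample_id == sample or sp.also_in_unaffected == sample:
                spike_refs.append((k, ReferenceMEI(
                    chrom=sp.chrom, breakpoint=sp.breakpoint, mei_class=MEIClass.ALU)))
        sample_truth = truth + [r for _, r in spike_refs]
        for tool, profile in cc.tool_profiles.items():
            sim = simulate_tool_calls(sample_truth, profile, rng, sample_id=sample,
                                      tool=tool, genome=config.genome,
                                      class_mix=config.class_mix)
            if len(sim.callset):
                callsets.append(sim.callset)
            for (k, _), was_emitted in zip(spike_refs, sim.emitted[len(truth):]):
                if was_emitted and spikes[k].sample_id == sample:
                    spikes[k].emitted_by.add(tool)

    sites = merge_callsets(callsets, tolerance=50, class_aware=True)
    cohort = CohortTable(samples=meta, sites=sites)
    return CohortSim(cohort=cohort, callsets=callsets, sites=sites,
                     targets=targets, genes=genes, panels=panels,
                     known_sites=polymorphic, spikes=spikes,
                     polymorphic_frequencies=freqs, config=config)
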