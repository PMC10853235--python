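"""Diagnostic prioritisation cascade over a cohort."""

import pandas as pd
import pytest

from meibench.cohort import (CohortTable, GeneAnnotation, PrioritizationConfig,
                             carrier_frequency, exclude_known_sites,
                             exclude_unaffected_carriers, frequency_filter,
                             panel_filter, prioritize)
from meibench.merging import MergedSite
from meibench.model import MEIClass, ReferenceMEI, TargetRegionSet
from meibench.simulate import CohortConfig, SimConfig, simulate_cohort


def _site(bp, carriers, chrom="1", cls=MEIClass.ALU):
    return MergedSite(chrom=chrom, representative_breakpoint=bp, mei_class=cls,
                      members=[(s, "melt", bp) for s in carriers])


def _cohort(n=10_000, n_affected=None, sites=()):
    n_affected = n if n_affected is None else n_affected
    df = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "family_id": [f"F{i}" for i in range(n)],
        "affected": [i < n_affected for i in range(n)],
        "panel": ["panelA" if i < n_affected else "" for i in range(n)],
    })
    return CohortTable(samples=df, sites=list(sites))


class TestCarrierFrequency:
    def test_strict_threshold_excludes_boundary(self):
        cohort = _cohort(10_000)
        at_boundary = _site(100, [f"S{i}" for i in range(3)])
        below = _site(900, [f"S{i}" for i in range(2)])
        assert carrier_frequency(at_boundary, cohort) == pytest.approx(0.0003)
        kept = frequency_filter([at_boundary, below], cohort, max_frequency=0.0003)
        assert kept == [below]

    def test_zero_carriers(self):
        assert carrier_frequency(_site(100, []), _cohort(100)) == 0.0

    def test_retained_at_threshold_implies_retained_at_higher(self):
        cohort = _cohort(1000)
        sites = [_site(100 + 200 * k, [f"S{i}" for i in range(k)]) for k in range(6)]
        for t in (0.001, 0.002, 0.004):
            kept_t = set(id(s) for s in frequency_filter(sites, cohort, t))
            kept_2t = set(id(s) for s in frequency_filter(sites, cohort, 2 * t))
            assert kept_t <= kept_2t


class TestKnownSiteExclusion:
    known = [ReferenceMEI("1", 1000, MEIClass.ALU)]

    def test_site_at_known_position_removed(self):
        assert exclude_known_sites([_site(1000, ["S1"])], self.known) == []

    def test_site_51bp_away_kept(self):
        kept = exclude_known_sites([_site(1051, ["S1"])], self.known)
        assert len(kept) == 1
        assert exclude_known_sites([_site(1050, ["S1"])], self.known) == []

    def test_empty_known_list_is_identity(self):
        sites = [_site(1000, ["S1"])]
        assert exclude_known_sites(sites, []) == sites

    def test_class_aware_by_default(self):
        l1_site = _site(1000, ["S1"], cls=MEIClass.L1)
        assert exclude_known_sites([l1_site], self.known) == [l1_site]
        assert exclude_known_sites([l1_site], self.known, class_aware=False) == []


class TestUnaffectedExclusion:
    def test_affected_only_site_kept(self):
        cohort = _cohort(10, n_affected=5)
        sites = [_site(100, ["S0", "S1"])]
        assert exclude_unaffected_carriers(sites, cohort) == sites

    def test_single_unaffected_carrier_removes_site(self):
        cohort = _cohort(10, n_affected=5)
        assert exclude_unaffected_carriers([_site(100, ["S0", "S7"])], cohort) == []

    def test_all_affected_cohort_is_identity(self):
        cohort = _cohort(10)
        sites = [_site(100, ["S0", "S9"])]
        assert exclude_unaffected_carriers(sites, cohort) == sites

    def test_unknown_carrier_status_is_an_error(self):
        cohort = _cohort(5)
        with pytest.raises(KeyError, match="S99"):
            exclude_unaffected_carriers([_site(100, ["S99"])], cohort)


class TestPanelFilter:
    # one gene with exons [1000,1150) and [3000,3150)
    genes = GeneAnnotation([("1", 1000, 1150, "GENE1"), ("1", 3000, 3150, "GENE1")])
    panels = {"panelA": {"GENE1"}, "panelB": {"OTHER"}}

    def _run(self, site, exonic_splice_only, cohort=None):
        cohort = cohort or _cohort(10)
        return panel_filter([site], cohort, self.genes, self.panels,
                            exonic_splice_only=exonic_splice_only)

    def test_exonic_site_kept_in_both_modes(self):
        site = _site(1100, ["S0"])
        assert self._run(site, False) == [site]
        assert self._run(site, True) == [site]

    def test_deep_intronic_site_removed_only_in_exonic_mode(self):
        site = _site(2200, ["S0"])  # >50 bp from both exons, inside gene span
        assert self._run(site, False) == [site]
        assert self._run(site, True) == []

    def test_splice_region_counts_as_exonic(self):
        site = _site(1155, ["S0"])  # 5 bp past the exon end, inside ±8 splice pad
        assert self._run(site, True) == [site]

    def test_gene_outside_carrier_panel_removed(self):
        cohort = _cohort(10)
        cohort.samples.loc[0, "panel"] = "panelB"
        cohort = CohortTable(samples=cohort.samples)
        site = _site(1100, ["S0"])
        assert panel_filter([site], cohort, self.genes, self.panels) == []

    def test_unknown_panel_name_is_an_error(self):
        cohort = _cohort(10)
        cohort.samples.loc[0, "panel"] = "nonexistent"
        cohort = CohortTable(samples=cohort.samples)
        with pytest.raises(KeyError, match="nonexistent"):
            panel_filter([_site(1100, ["S0"])], cohort, self.genes, self.panels)


class TestPrioritize:
    def _sim(self, seed, **cohort_kw):
        cfg = SimConfig(seed=seed, cohort=CohortConfig(**cohort_kw))
        return simulate_cohort(cfg)

    def test_spiked_site_is_the_only_candidate(self):
        sim = self._sim(11, n_samples=300, n_affected=200,
                        n_polymorphic_sites=25, site_frequency_range=(0.01, 0.05))
        res = prioritize(sim.cohort, sim.prioritization_config())
        got = {(r.sample_id, r.genes) for r in res.candidates.itertuples()}
        assert got == sim.expected_candidate_samples()

    def test_spike_also_in_unaffected_yields_zero_candidates(self):
        sim = self._sim(12, n_samples=200, n_affected=120,
                        n_pathogenic_spikes=1, n_spikes_in_unaffected=1)
        res = prioritize(sim.cohort, sim.prioritization_config())
        assert len(res.candidates) == 0
        assert sim.expected_candidate_samples() == set()

    def test_pass_through_config_keeps_all_target_sites(self):
        sim = self._sim(13, n_samples=100, n_affected=100)
        config = PrioritizationConfig(targets=sim.targets, known_sites=(),
                                      genes=None, max_frequency=None)
        res = prioritize(sim.cohort, config)
        from meibench.cohort import restrict_sites_to_targets
        assert len(res.sites) == len(restrict_sites_to_targets(sim.sites, sim.targets))

    def test_cascade_is_monotone_decreasing_and_ordered(self):
        sim = self._sim(14, n_samples=150, n_affected=100)
        res = prioritize(sim.cohort, sim.prioritization_config())
        counts = [n for _, n in res.stage_log]
        assert counts == sorted(counts, reverse=True)
        assert [s for s, _ in res.stage_log] == [
            "input", "target_regions", "unaffected_excluded",
            "known_sites_excluded", "frequency", "panel"]

    def test_exonic_splice_mode_is_a_subset(self):
        sim = self._sim(15, n_samples=150, n_affected=100)
        loose = prioritize(sim.cohort, sim.prioritization_config(False))
        strict = prioritize(sim.cohort, sim.prioritization_config(True))
        assert set(id(s) for s in strict.sites) <= set(id(s) for s in loose.sites)


def test_cohort_table_rejects_unknown_carriers_and_duplicates():
    df = pd.DataFrame({"sample_id": ["A", "A"], "family_id": ["F", "F"],
                       "affected": [True, True], "panel": ["", ""]})
    with pytest.raises(ValueError, match="duplicate"):
        CohortTable(samples=df)
    df2 = pd.DataFrame({"sample_id": ["A"], "family_id": ["F"],
                        "affected": [True], "panel": [""]})
    with pytest.raises(ValueError, match="carriers"):
        CohortTable(samples=df2, sites=[_site(100, ["ZZ"])])
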