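"""Read-support filtering: fixed thresholds and F-score grid search."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from meibench.benchmark import benchmark
from meibench.filtering import (FilterSpec, apply_filter, common_filter_spec,
                                default_grid, evaluate_on_holdout, optimize_filter)
from meibench.model import Assay, CallSet, MEICall, MEIClass
from meibench.simulate import SimConfig, simulate_tool_calls, simulate_truth, uniform_profile


def _call(total, sr, quality=None, flags=(), bp=100):
    return MEICall(sample_id="S", chrom="1", breakpoint=bp, mei_class=MEIClass.ALU,
                   split_reads=sr, discordant_pairs=total - sr, quality=quality,
                   flags=frozenset(flags))


class TestCommonSpec:
    def test_exome_thresholds(self):
        spec = common_filter_spec(Assay.ES)
        assert (spec.min_total_support, spec.min_split_reads) == (5, 2)

    def test_genome_thresholds(self):
        spec = common_filter_spec("GS")
        assert (spec.min_total_support, spec.min_split_reads) == (10, 2)

    def test_vacuous_spec_passes_everything(self):
        cs = CallSet(calls=[_call(0, 0), _call(3, 1)])
        assert len(apply_filter(cs, FilterSpec(0, 0))) == 2


class TestApplyFilter:
    es = common_filter_spec(Assay.ES)

    def test_boundary_inclusive(self):
        assert len(apply_filter(CallSet(calls=[_call(5, 2)]), self.es)) == 1

    def test_below_total_threshold_removed(self):
        assert len(apply_filter(CallSet(calls=[_call(4, 2)]), self.es)) == 0

    def test_below_sr_threshold_removed(self):
        assert len(apply_filter(CallSet(calls=[_call(9, 1)]), self.es)) == 0

    def test_drop_flag_removes_call(self):
        spec = FilterSpec(0, 0, drop_flags=frozenset({"ac0"}))
        cs = CallSet(calls=[_call(9, 5, flags=("ac0",)), _call(9, 5)])
        kept = apply_filter(cs, spec)
        assert len(kept) == 1 and not kept[0].flags

    def test_quality_threshold(self):
        spec = FilterSpec(0, 0, min_quality=20.0)
        cs = CallSet(calls=[_call(5, 2, quality=10.0), _call(5, 2, quality=20.0),
                            _call(5, 2, quality=None)])
        assert len(apply_filter(cs, spec)) == 2  # missing quality passes

    def test_idempotent(self, rng):
        cs = CallSet(calls=[_call(int(t), int(s))
                            for t, s in zip(rng.integers(0, 15, 100),
                                            rng.integers(0, 5, 100)) if s <= t])
        once = apply_filter(cs, self.es)
        assert apply_filter(once, self.es).calls == once.calls

    @given(st.integers(0, 12), st.integers(0, 6), st.integers(0, 12), st.integers(0, 6),
           st.integers(0, 41))
    def test_monotone_in_each_threshold(self, t1, s1, dt, ds, seed):
        rng = np.random.default_rng(seed)
        calls = []
        for _ in range(60):
            total = int(rng.integers(0, 15))
            sr = int(rng.integers(0, total + 1))
            calls.append(_call(total, sr))
        cs = CallSet(calls=calls)
        lax = apply_filter(cs, FilterSpec(t1, s1))
        strict = apply_filter(cs, FilterSpec(t1 + dt, s1 + ds))
        assert len(strict) <= len(lax)
        assert set(id(c) for c in strict) <= set(id(c) for c in lax)


def _train_instance(seed, n_truth=120):
    config = SimConfig(seed=seed, n_truth=n_truth,
                       genome=[("1", 5_000_000)])
    truth = simulate_truth(config)
    profile = uniform_profile(0.8, fp_per_mb=8.0, breakpoint_sd=3.0,
                              support_mean=8.0, sr_fraction=0.5)
    sim = simulate_tool_calls(truth, profile, seed + 1, genome=config.genome)
    return sim.callset, truth


class TestOptimize:
    def test_single_spec_grid_returns_it(self):
        calls, truth = _train_instance(0)
        spec = FilterSpec(3, 1)
        res = optimize_filter(calls, truth, [spec])
        assert res.best_spec == spec

    def test_spec_removing_all_calls_never_beats_positive_f(self):
        calls, truth = _train_instance(1)
        killer = FilterSpec(10**6, 0)
        res = optimize_filter(calls, truth, [killer, FilterSpec(0, 0)])
        killer_f = dict((s, m.f_score) for s, m in res.table)[killer]
        assert killer_f == 0.0
        assert res.best_spec != killer

    @pytest.mark.parametrize("seed", range(5))
    def test_argmax_equals_exhaustive_reevaluation(self, seed):
        calls, truth = _train_instance(seed + 10, n_truth=80)
        grid = [FilterSpec(t, s, q) for t in (2, 5, 8) for s in (0, 1, 2)
                for q in (None, 5.0)]
        res = optimize_filter(calls, truth, grid)
        # independent loop, re-running filter + match per grid point
        best = None
        for spec in grid:
            m = benchmark(apply_filter(calls, spec), truth)
            prec = m.precision if m.precision == m.precision else -1.0
            key = (m.f_score, prec, -spec.min_total_support, -spec.min_split_reads)
            if best is None or key > best[0]:
                best = (key, spec)
        assert res.best_spec == best[1]
        assert res.best_f == pytest.approx(best[0][0])

    def test_best_f_at_least_common_spec_f(self):
        calls, truth = _train_instance(3)
        grid = default_grid(calls) + [common_filter_spec(Assay.ES)]
        res = optimize_filter(calls, truth, grid)
        common_f = benchmark(apply_filter(calls, common_filter_spec(Assay.ES)),
                             truth).f_score
        assert res.best_f >= common_f


class TestHoldout:
    def test_vacuous_spec_on_perfect_predictions(self):
        config = SimConfig(seed=7, n_truth=50, genome=[("1", 2_000_000)])
        truth = simulate_truth(config)
        sim = simulate_tool_calls(truth, uniform_profile(1.0, fp_per_mb=0.0,
                                                         breakpoint_sd=0.0),
                                  8, genome=config.genome)
        m = evaluate_on_holdout(FilterSpec(0, 0), sim.callset, truth)
        assert m.f_score == 1.0

    def test_identical_train_test_reproduces_best_f(self):
        calls, truth = _train_instance(4)
        res = optimize_filter(calls, truth)
        m = evaluate_on_holdout(res.best_spec, calls, truth)
        assert m.f_score == pytest.approx(res.best_f)

    def test_holdout_f_not_above_train_f_in_median(self):
        """Thresholds tuned on one noisy dataset should generalise with no
        gain, in the median over independent replicates."""
        diffs = []
        for seed in range(20):
            train_calls, train_truth = _train_instance(100 + seed)
            test_calls, test_truth = _train_instance(200 + seed)
            res = optimize_filter(train_calls, train_truth)
            hold = evaluate_on_holdout(res.best_spec, test_calls, test_truth)
            diffs.append(hold.f_score - res.best_f)
        assert np.median(diffs) <= 1e-9
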