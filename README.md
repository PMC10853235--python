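# meibench

Post-caller analysis toolkit for **mobile element insertions (MEIs)** —
non-reference Alu, L1 and SVA retrotransposon insertions detected in
short-read exome (ES) or genome (GS) sequencing. MEI callers emit
heterogeneous output (VCF, BED, tab-delimited text) with very different
precision/sensitivity trade-offs, and clinically relevant insertions are
rare events buried among thousands of common polymorphisms. `meibench`
provides the computational layer that sits downstream of the callers:

- **normalisation** of call sets into a unified model (1-based
  breakpoints, element class, split-read/discordant-pair support);
- **truth-set benchmarking** with TSD-aware matching windows and
  precision / sensitivity / F-score, overall and per element class;
- **read-support filtering**: the fixed "common" thresholds
  (ES: ≥5 supporting reads with ≥2 split reads; GS: ≥10 with ≥2) and an
  **optimised** strategy that grid-searches threshold combinations for
  maximal F-score on a training benchmark, then applies them to held-out
  data;
- **multi-tool merging** into unique MEI sites with a ±50 bp
  single-linkage tolerance, plus tool-concordance and combined
  detection-rate statistics;
- the **rare-disease prioritisation cascade**: target-region
  restriction → unaffected-carrier exclusion → known-polymorphism
  (dbRIP-style) exclusion → carrier-frequency filter → gene-panel filter
  (optionally exonic/splice-region only);
- **diagnostic-yield statistics**: Wald 95% confidence intervals on
  diagnosis rates, Fisher exact cohort comparison, and per-tool clinical
  sensitivity on validated diagnostic cases;
- a **synthetic-data generator** that emulates truth sets (~88% Alu /
  9% L1 / 3% SVA), per-tool call sets (class-specific sensitivity,
  breakpoint jitter, negative-binomial read support, uniform false
  positives) and whole cohorts with ground-truth bookkeeping, so the
  entire pipeline is testable without any sequencing data.

## The model in brief

A predicted call at position *x* is a **true positive** for reference
insertion *r* when *x* lies in *r*'s matching window: the target site
duplication (TSD) interval padded by ±10 bp when the TSD is resolved,
else ±50 bp around the reference breakpoint. TPs are counted at the
prediction level, FNs at the reference level, and

    sensitivity = TP / (TP + FN),   precision = TP / (TP + FP),
    F = 2 · precision · sensitivity / (precision + sensitivity).

Diagnostic yield *k/n* is reported with the Wald interval
*p ± z·√(p(1−p)/n)*, clipped at 0, and carrier frequency of a merged
site is the fraction of cohort samples supporting it; only sites
strictly below the rarity threshold survive the cascade.

## Worked example

```python
import meibench as mb

config = mb.SimConfig(seed=11, n_truth=500, genome=[("1", 20_000_000)])
truth = mb.simulate_truth(config)
sim = mb.simulate_tool_calls(truth, mb.ES_TOOL_PRESETS["toolA"], 12,
                             sample_id="S1", tool="toolA", genome=config.genome)

raw = mb.benchmark(sim.callset, truth)
common = mb.benchmark(mb.apply_filter(sim.callset, mb.common_filter_spec("ES")), truth)
opt = mb.optimize_filter(sim.callset, truth)
print(f"raw:      precision={raw.precision:.3f} sensitivity={raw.sensitivity:.3f} F={raw.f_score:.3f}")
print(f"common:   precision={common.precision:.3f} sensitivity={common.sensitivity:.3f} F={common.f_score:.3f}")
print(f"optimised: best spec total>={opt.best_spec.min_total_support} "
      f"SR>={opt.best_spec.min_split_reads}  F={opt.best_f:.3f}")
print("yield:", mb.wald_ci(3, 6247).render_percent())
```

prints

```
raw:      precision=0.966 sensitivity=0.686 F=0.802
common:   precision=0.979 sensitivity=0.558 F=0.711
optimised: best spec total>=2 SR>=0  F=0.792
yield: 0.048% [0.000%–0.102%]
```

The simulated exome caller detects ~69% of the 500 truth insertions with
high precision; the fixed ES filter buys a little precision at a visible
sensitivity cost, while the grid search — free to choose laxer
thresholds — lands near the unfiltered optimum for this (already
precise) caller. The last line is the diagnostic yield of a cohort with
3 diagnoses among 6247 affected cases, with its Wald 95% CI.

The same operations are exposed as a CLI:

```
meibench simulate --seed 1 --out-dir sim/
meibench normalize --in calls.vcf --format vcf --sample S1 --tool melt --out calls.tsv
meibench filter --in calls.tsv --spec common-es --out filtered.tsv --stage-log stages.json
meibench benchmark --pred filtered.tsv --truth truth.tsv --report metrics.json
meibench merge --in a.tsv b.tsv --tolerance 50 --out sites.tsv
meibench prioritize --sites ... --cohort meta.tsv --targets exons.bed \
    --known dbrip.tsv --genes genes.tsv --panels panels.tsv --out candidates.tsv
meibench stats yield --hits 3 --n 6247
```

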