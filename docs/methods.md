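# Methods

This note documents the models, conventions and design choices behind
`meibench`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic data does and does
not emulate.

## Coordinates and the call model

All breakpoints are 1-based single positions. BED inputs convert
`start+1`; BED records spanning more than one base (some callers report
wide insertion intervals) are collapsed to the lower-median midpoint
`(start + end + 1) // 2`, since the downstream evaluation treats every
call as a point insertion. Chromosome names are compared after
stripping a `chr` prefix, so GRCh37 dialects mix safely. Read support
is split into split/clipped reads (SR, junction-spanning evidence) and
discordant pairs (DP, mate-in-element evidence); `total_support = SR +
DP` is the quantity filters act on. Formats that report no support at
all (plain BED) yield calls flagged `support_unknown` with zero counts:
conservative by default (they fail read-support filters), but
`apply_filter(..., exempt_unknown_support=True)` lets them bypass the
support thresholds when a tool genuinely does not report them.

All ±N windows in the package (matching fallback, target-region pad,
merge tolerance, known-site pad, panel pad) are closed at both
boundaries: a call exactly N bp away is inside.

## Matching and metrics

A reference insertion's matching window is the TSD interval padded by
±10 bp when the TSD is resolved, else ±50 bp around the breakpoint. The
±10 pad is applied around the whole TSD interval (not each end
separately). Each prediction is assigned to at most one reference: the
eligible reference with the nearest breakpoint, ties broken by lower
reference coordinate, then by reference input order — the last
tie-break matters only when two references share a coordinate, but it
is what makes assignment fully deterministic and lets an all-pairs
brute-force oracle reproduce the interval-indexed implementation
pair-for-pair. A reference may absorb several nearby predictions: all
of them count as TPs (precision is prediction-level) while the
reference counts once as detected (sensitivity is reference-level).
Consequently `TP + FP = #predictions` and `detected + FN = #references`
hold exactly.

Element-class agreement (an Alu prediction cannot match an L1 truth) is
required by default, with unknown-class predictions compatible with
everything; `require_class=False` disables it. Metrics with an empty
denominator (precision with zero predictions, sensitivity with zero
references) are NaN markers and force F = 0. Per-class metrics
restrict by class: a matched prediction counts toward its reference's
class; an unmatched prediction counts as an FP of its own class;
unmatched unknown-class predictions belong to no class.

## Filtering

The fixed filter is (total ≥ 5, SR ≥ 2) for exomes and (total ≥ 10,
SR ≥ 2) for genomes, thresholds inclusive; caller flags (e.g. `ac0`)
can be added as drop criteria, and a quality floor applies only to
calls that carry a quality score (quality scales are tool-specific, so
a single "larger is better" real is all the model assumes). The
optimised strategy evaluates a grid — default: total ∈ {2,3,5,8,10} ×
SR ∈ {0,1,2,4} × quality ∈ {none, data median} — by filter → match →
score, and selects the maximal F-score; ties go to higher precision,
then lower total threshold, then lower SR threshold (prefer the laxer
filter when nothing distinguishes them — F-ties are common on small
truth sets). Holdout evaluation applies the trained spec with no
refitting.

## Merging

Calls merge into unique sites by single-linkage per chromosome (and per
element class by default): sorted breakpoints chain while consecutive
gaps are ≤ 50 bp. The linkage is transitive, so a dense chain can span
more than 50 bp end-to-end; the guarantee is on consecutive gaps. The
representative breakpoint is the lower median of member breakpoints;
the consensus class is the majority vote among members (ties →
unknown). Class-aware merging keeps co-located Alu and L1 sites
distinct, matching how unique sites are counted per class; an
`class_aware=False` mode merges regardless. Tool concordance is
Jaccard-style: sites supported by both tools over sites supported by
either. The combined detection rate counts a truth entry as detected
when any member or representative breakpoint falls in its matching
window.

## The prioritisation cascade

Stages run in a fixed order, each only removing sites:

1. target-region restriction (representative breakpoint within ±50 bp
   of an exon/capture interval);
2. removal of any site carried by an unaffected sample (a literal
   reading: one unaffected carrier disqualifies the site);
3. removal of sites within ±50 bp (class-aware) of a known polymorphic
   insertion locus;
4. carrier-frequency filter: carriers/samples strictly below the
   threshold, computed over **all** cohort samples from the site's full
   carrier set — the frequency is a property of the cohort, unaffected
   by earlier exclusions. Frequency is per sample, not per family
   (switchable in principle by collapsing carriers to families before
   counting);
5. gene-panel filter: the site must hit (±50 bp) a gene in the panel of
   at least one carrier; in exonic/splice mode the hit must touch an
   exon or its ±8 bp splice region. The 8 bp splice pad is a
   configurable stand-in — there is no universal definition of "splice
   site" width; ±8 covers the canonical donor/acceptor motifs.

Per-stage survivor counts are logged (and written as JSON by the CLI)
so a cascade can be audited. The default rarity threshold is 0.03%,
appropriate for cohorts of thousands to tens of thousands of samples
where even a handful of carriers exceeds it. For the synthetic cohorts
(500 samples) that threshold would exclude every site including a
single-carrier pathogenic spike (1/500 = 0.2%), so the simulator's
prioritisation config uses 0.5% — the nominal lower edge of its common
polymorphic-frequency band — as the rare/common boundary; the
threshold's role (pass rare spikes, fail common polymorphisms) is
identical, only the scale differs with cohort size.

Visual inspection and genotype–phenotype adjudication are deliberately
out of scope: the cascade ends in a candidate report (one row per
affected carrier and surviving site, with genes hit, carrier counts and
supporting tools), which is where a human takes over.

## Synthetic data

The generator produces the statistical structure the pipeline consumes,
not reads or sequences.

**Truth sets.** Sites are uniform per chromosome (multinomial across
chromosomes by length) with > 200 bp spacing, so matching windows never
overlap and every label is unambiguous. Classes are drawn from
0.88/0.09/0.03 (Alu/L1/SVA), the mix observed in curated exome truth
sets. TSD intervals of 5–20 bp containing the breakpoint are attached
with probability 0.8 (long-read-curated truth knows most TSDs; the rest
fall back to the ±50 bp window).

**Caller emulation.** Each truth site is emitted with a class-specific
sensitivity; the emitted breakpoint adds rounded N(0, sd) jitter — a
rare large excursion leaves the matching window and becomes a coupled
FN + FP, which is exactly how real callers lose near-boundary events.
Read support is negative-binomial (over-dispersion typical of capture
data; the distribution's tail, not its exact shape, is what threshold
filters see), split binomially into SR and DP by `sr_fraction` — an
SR-only caller is `sr_fraction ≈ 0.9`, a DP-heavy genome caller ≈ 0.4.
False positives are Poisson per megabase, placed uniformly but never
within 100 bp of a truth site (outside every matching window, so FP
labels are exact), with lower support (mean/3) than true calls — which
is why support filters help. The two bundled exome presets differ the
way the two best exome callers do: one trades lower SVA/L1 sensitivity
(poly-A-only captures) for split-read-dominated evidence, the other
leverages DPs. ES vs GS is a matter of presets (support means,
sensitivities), not read-level simulation.

**Cohorts.** 500 samples (350 affected) by default, each its own
family; affected samples carry one of two gene panels built over a
synthetic annotation of 30 five-exon genes. 40 polymorphic loci get
nominal frequencies uniform in 0.5–5% and per-sample Bernoulli
carriers; the same loci double as the known-polymorphism exclusion
list, mirroring how common insertions are catalogued. One pathogenic
Alu spike is placed centrally in an exon of a gene from its carrier's
own panel, ≥ 250 bp from any polymorphic locus; optionally a spike is
also injected into an unaffected sample to exercise stage 2. Cohort
caller profiles use sensitivity 0.85–0.90 and a zero FP rate: spike
recovery is then exact by construction — a random FP landing in a
panel-gene exon of an affected sample would be a *legitimate*
candidate, indistinguishable from a true rare event without the
wet-lab follow-up that is out of scope. The bookkeeping records which
spikes each tool emitted, so the expected candidate set is known
exactly.

What passing the synthetic tests does **not** show: robustness to
coverage heterogeneity, capture-kit batch effects, mapping artefacts in
repetitive regions, clustered truth sites closer than 200 bp, or
tool-specific quality-score semantics. The generator's labels are
clean; real call sets are not.

## Statistics

The confidence interval on a diagnostic yield k/n is the Wald
(normal-approximation) interval p ± z·√(p(1−p)/n) with the lower bound
clipped at 0 — chosen because it exactly reproduces the published
per-cohort intervals it is checked against, which identifies it as the
method behind them; percent renderings round half-up to 3 decimals. At
p = 0 the Wald half-width collapses to zero, a known weakness of the
method that the clipping convention makes explicit rather than hiding.
The Fisher exact test is two-sided by the probability-mass definition
(sum of hypergeometric probabilities ≤ the observed table's), computed
via scipy and cross-checked in the tests against full enumeration over
the margin-constrained tables. Clinical sensitivity is the per-tool
fraction of validated diagnostic cases detected; concordance is the
fraction detected by every tool. The ten published validated cases
ship with the package (`meibench/data/diagnostic_cases.tsv`) as the
standard input for those statistics.

## Problem sizes and determinism

All simulations are driven by `numpy.random.default_rng` seeds;
identical seeds give byte-identical outputs. The bundled verification
runs use desk-scale sizes — 1000 random matching instances of ≤ 50
calls, 100 grid-search instances of 60 truth sites, one 2000-site
parameter-recovery run on a 50 Mb genome, 50 cohorts of 500 samples —
chosen so the whole suite replays in well under a minute while keeping
binomial error bars tight enough for 3σ checks. Parameter-recovery
runs use 3 bp breakpoint jitter so that window-misses are negligible
against binomial error and the measurement isolates the configured
sensitivity; the benchmark presets keep 5 bp, where jitter misses are
an intended error mechanism.
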