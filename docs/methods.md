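# Methods

This note documents the generative models, the physical design of the
warehouse, the exact semantics of the query suite, and the numerical
and design choices behind them.

## Synthetic reference world

**Geography.** Four world regions (Europe, Americas, Asia, Africa) map
1:1 to the four ethnic groups (EUR, AMR, EAS, AFR).  Countries (default
181, the granularity at which real resources stop reporting allele
frequencies) are split into subregions of up to six countries and get
log-normal population sizes (log-mean 16, log-sd 1.3, floor 10⁴), so
population-weighted sampling is heavy-tailed and nontrivial.  The
hierarchy is functional by construction: country → subregion → region.

**Gene models.** Gene loci and exon unions form a shared skeleton laid
out cyclically over chromosomes 1–22, X, Y (synthetic lengths roughly
proportional to the karyotype): per gene, 1 + Poisson(mean − 1) exons of
80–400 bp separated by 200–3000 bp introns, with 5–50 kb intergenic
gaps.  Each annotation source (Ensembl-like, RefSeq-like) derives its
own transcripts from the skeleton — a canonical transcript covering all
exons, up to two alternative transcripts over contiguous exon subsets,
and exactly one merged transcript equal to the exon union.  Sharing the
skeleton makes merged footprints coincide across sources, which
guarantees that every catalog variant is exonic in *both* sources; the
transcript structures themselves are drawn independently per source.

**Variant catalog.** SNV positions are drawn uniformly without
replacement over merged-exon base pairs (hence unique and exonic by
construction).  Allele frequencies use a hierarchical model: a base AF
per variant from Beta(0.25, 4.75) — mean 0.05, strongly right-skewed,
so most variants are rare — jittered per ethnic group by N(0, 0.5) on
the logit scale.  The shared base induces the positive cross-group
correlation seen in real population panels (tested: logit-scale
correlation > 0.5); the jitter creates population-specific
polymorphisms.  Real frequency resources publish observed values, not a
generative law, so these hyperparameters are the package's own choice,
fixed once.  Each variant carries a damaging/tolerated call (Bernoulli,
default fraction 0.2), placeholder predictor scores, and a site mean
depth from Gamma(shape 10, scale 6) — mean 60×, typical of exome
capture.

**Diseases.** Unique synthetic six-digit OMIM-like identifiers; the
default list size (7569) matches the scale of a curated Mendelian
disease catalog.  Disease labels are attached to samples at a
configurable prevalence (default 0.2, uniform over diseases); how a
real registry would assign them is outside the data model, so
prevalence is deliberately a knob rather than a claim.

## Cohort simulation

Three steps per the design: (1) samples → groups (default uniform
proportions; configurable) and, within a group, countries multinomially
by population; (2) per (sample, variant), a genotype from the
Hardy–Weinberg probabilities (1 − 2af + af², 2af(1 − af), af²) at the
sample's group AF — evaluated exactly in that form; (3) depths
DP ~ Poisson(site mean), AD | DP = Binomial(DP, ½) for 0/1 and
DP − Binomial(DP, ε), ε = 0.01, for 1/1.  Genotype-likelihood fields
are carried as null placeholders (no generative model is defined for
them).  Only non-reference calls are emitted, streamed in
(sample, chromosome, position) order; a 200 × 5000 run yields ~96 000
fact rows, matching the analytic expectation Σ(1 − P(0/0)).

Randomness: every component draws from its own stream derived from the
user seed via `SeedSequence` with a component tag, so the pipeline is
bit-reproducible end to end (verified down to byte-identical Parquet
files) and adding a component never perturbs another's stream.

## Warehouse physical design

Tables are Parquet (default) or ORC, codec ∈ {none, snappy, gzip}
(snappy by default: effectively free decompression at query time),
registered in a JSON catalog standing in for a metastore.  The fact
table is partitioned by chromosome and sorted by (chrom, ref, alt,
sample_id) within partitions — sorting low-cardinality columns first
improves run-length/dictionary compression.  Level 2 groups genotype
counts by (variant, country, disease), carrying all dimension FKs and
an artificial surrogate key (some storage engines require an explicit
primary key on aggregate tables).  Level 3 replaces every FK with the
dimension attributes.  Loads reject (and count) records with
unresolvable FKs; level-3 building fails fast on dangling FKs, since by
then the data is supposed to be clean.

The cube precomputes group-bys of level 3 along declared hierarchies
(region → subregion → country; gene → transcript → exon of the merged
Ensembl model) for measures n_het, n_homalt, n_records and allele
count.  Cuboids exist for every hierarchy prefix plus the apex; any
other grouping raises an explicit reroute signal instead of silently
recomputing — mirroring how cube engines fall back to a runtime engine.

## Query semantics and conventions

Decisions that were genuinely open, fixed as follows and applied
identically in SQL templates and oracles:

- **AF denominator** is 2 × (samples in the group, from the registry);
  absent fact rows are reference-homozygous.  A variant observed in the
  cohort but absent from a group yields an explicit AF-0 row.  The
  group universe is the set of groups with ≥ 1 sample.
- **Rarity (Q2)** is judged on the overall cohort AF, cutoff
  parameterized (default 0.01); the damaging filter can be switched off
  (then Q2 degenerates to distinct-variant counts per region, which is
  cross-checked against an independent count in the tests).
- **Region membership** is point containment pos ∈ [start, end],
  1-based inclusive.  A-subqueries use canonical transcripts,
  B-subqueries the exons of merged transcripts; both interval-join the
  gene-model dimension at every storage level (the merged-exon FK
  carried in the fact rows identifies one exon, but transcript-level
  grouping requires the join).
- **Q4 (coverage distribution)** summarizes the *site mean depth* —
  the per-variant annotation carried in the predictions dimension —
  weighted by the genotype calls in the region, with min/q25/median/
  q75/max under linear interpolation between closest ranks.  Summaries
  of a variant-level attribute are exactly computable from the count
  aggregates, so all three storage levels answer identically; the
  per-call simulated DP remains in the raw table and drives Q5 and Q8.
  SQL engines disagree on quantile conventions, so the engine path
  returns (group, depth, weight) rows and one shared post-processing
  step computes the quantiles — cross-engine reproducibility over
  dialect fidelity.
- **Q6** does not collapse strand-complementary substitution types by
  default; a collapse mode (pyrimidine-reference classes) is available.
- **Q3** counts genotype calls (records); it filters by OMIM id at
  every level because the denormalized table carries attributes, not
  FKs.
- **Ordering**: results are sorted by their full key tuple before any
  comparison; real-valued measures compare at 10⁻⁹ relative tolerance
  (floating-point sums depend on accumulation order), keys and counts
  exactly.

Templates are shipped as text files with named placeholders plus one
YAML descriptor per query (levels, parameters, render options, sort
keys).  Rendering is injection-safe: identifier choices are validated
against whitelists, value parameters are bound as escaped literals.
Q5–Q12 run on the raw level only (they need call granularity);
requesting them elsewhere is an explicit unsupported-pair error — which
the harness records as a failed cell rather than aborting.

## Benchmark harness

The harness is read-only over the warehouse.  Each (query, engine,
format, codec, level) combination runs `repetitions` times (default 5,
the usual small-repetition benchmark convention); wall-clock time and
result cardinality are recorded per run, and optional verification
compares cardinality against the oracle, flagging divergent engines.
Summaries report mean/min/max per combination — the min/max become the
error bars in the plots.  Timings are warm-cache; an OS cache-purge
hook can be injected for cold runs but is off by default and
platform-dependent.  The default engine adapter loads the columnar
tables into in-memory SQLite; the adapter contract (open / submit SQL
text / fetch typed rows / close) admits remote engines without touching
the harness.

## What the synthetic data does and does not show

The generator reproduces the *structural* properties that matter for
storage benchmarking — population-stratified Hardy–Weinberg genotypes
with realistic AF skew, exonic SNVs against two annotation sources,
exome-like per-sample yield, heavy-tailed country assignment — with
exact, seedable ground truth.  It does not model linkage disequilibrium,
indels or multi-allelic sites, phasing, genotype likelihoods, CNVs
(Q4's use-case is served by depth statistics alone), mutation-rate
heterogeneity along the genome, or realistic disease–variant
association (disease labels are independent of genotype).  Passing
correctness checks here therefore validates the relational machinery
and the simulator's calibration, not biological realism of any
particular query's output; absolute timings at this scale say nothing
about distributed engines on real hardware.

## Problem sizes

Unit tests use a 50 × 500 world; end-to-end checks use 200 samples ×
5000 catalog variants (~10⁵ fact rows) with full-size geography and
disease dimensions — large enough that every query family returns
non-trivial results (including rare-variant queries, whose AF quantum
1/2N must sit below the 1% cutoff) while the whole suite builds and
verifies in well under a minute on one core.  `scripts/acceptance.py`
uses the same 200 × 5000 conditions.
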