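# Methods

## Pipeline model

The package formalises a desk analysis that links a multi-herb decoction
to a treatment-response transcriptome in three layers.

**Ingredient screening.** Every herb–ingredient row carries three ADME
properties: oral bioavailability (OB, percent), drug-likeness (DL,
unitless 0–1) and Caco-2 permeability (unitless, possibly negative). A
row passes iff OB ≥ 20, DL ≥ 0.18 and Caco-2 ≥ 0; all three cutoffs are
inclusive.
Ingredient identity is name-based: names are whitespace-trimmed and
Unicode-NFC-normalised, then matched exactly — no chemistry-aware fuzzy
matching. When a database carries duplicated rows for one ingredient
with divergent ADME values, the ingredient enters a herb's passing set
if any of its rows passes (a deterministic, conservative rule). The
per-herb passing sets are unioned into the unique ingredient set, and
ingredients passing in ≥ 2 herbs form the overlap. On the reported
three-herb structure (24 + 20 + 102 selections with 11 names each shared
by exactly two herbs) this yields 135 unique ingredients; the
pairwise-sharing multiplicity is an inference consistent with those
counts, not hard-coded anywhere — the operations work for any
multiplicity structure.

**Target and PPI layer.** Compound→target mapping is a plain relational
restriction; compounds missing from the lookup are reported, never
raised, because exported target tables are routinely incomplete. The PPI
graph is an undirected simple graph with STRING-style combined scores
(0–1000): self-loops are dropped, A–B/B–A duplicates merge keeping the
maximum score, and edges below `ppi_score_min` (default 400, the
conventional STRING medium-confidence level — a design choice, since
the procedure being formalised fixes no threshold) are excluded.
Centrality is degree — the count of interaction partners, which is what
reading edge counts off a network figure measures — not betweenness or
closeness. Hubs are the top-k by degree (default k = 10) with the full
tie group at the boundary included, since hub membership in such
figures is visual and quantifies no cutoff.

**Rescue transcriptomics.** With groups sham (baseline), model and
treated, per-gene ratios are

    r_model  = (mean_model  + c) / (mean_sham + c)
    r_treated = (mean_treated + c) / (mean_sham + c)

with pseudocount c (default 1.0 expression unit; c = 0 is allowed on
strictly positive data and required to reproduce exact textbook ratios).
Group summary is the arithmetic mean by default (median available via
`group_summary`). Classification: up iff r_model ≥ 4 (inclusive), down
iff r_model < 1/4 (strict), rescued iff 1/4 < r_treated < 4 (both
strict) — the boundary semantics are deliberately asymmetric, so a gene
at exactly 4.0 is altered and a treated ratio of exactly 4.0 does not
rescue. Direction comes from the model group only; the treated group
never reassigns it. The headline percentage is rescued/altered, reported
to the nearest integer with the exact fraction alongside. The reference
breakdown this package reproduces is 206 up-altered with 115 rescued
plus 191 down-altered with 155 rescued: 270/397 ≈ 68.01 % → 68 %.
The analysis is
scale-invariant: multiplying all expression values by any c > 0 changes
no call (with pseudocount 0 or rescaled).

Heat-map export orders the altered genes by average-linkage hierarchical
clustering of their (log2 r_model, log2 r_treated) profiles under
Euclidean distance, via `scipy.cluster.hierarchy`; with fewer than two
altered genes the input order passes through.

**Concordance.** Predicted (human-style) and observed (mouse-style)
symbols are matched case-insensitively after trimming; an exact rule and
a user-supplied two-column ortholog table are alternatives. No ortholog
database is consulted — symbol-case matching is a proxy adequate for
symbols that differ only in capitalisation, and wrong for genuinely
diverged gene names; the Jaccard index emitted is a convenience score,
not a published quantity.

## Behavioral metrics and statistics

Spontaneous alternation counts overlapping windows of three consecutive
arm entries visiting three distinct arms, divided by (entries − 2) — the
window count — times 100. The discrimination ratio is
novel/(novel + familiar) × 100. Undefined metrics (< 3 entries, zero
total exploration) propagate as NaN and are dropped per group before
testing, never coerced to zero.

`group_compare` applies the normality-gated two-path procedure:
Shapiro–Wilk per group; if every group has p > α (default 0.05), one-way
ANOVA with pairwise pooled-variance t tests adjusted by Holm–Šidák
(`statsmodels.stats.multitest`); otherwise Kruskal–Wallis with Dunn's
post hoc. Dunn's procedure is implemented in-package (rank-sum z
statistics with tie-corrected variance, Bonferroni adjustment — the
classical form) because no installed library provides it. The gate is
deterministic given the data. Note the gate's side effect on the
omnibus: under a normal null some replicates route to Kruskal–Wallis,
but the combined type-I error stays at ≈ α (measured 0.04–0.06 over
1000 four-group, n = 5 null replicates).

## Synthetic data generator

The generator emulates the structure of each real input with planted
truth; all randomness in a call flows from one integer seed
(`numpy.random.default_rng`), so outputs are byte-identical across runs.

* Herb tables: exactly `round(pass_fraction × size)` passing ingredients
  per herb; passing rows draw OB ~ U(20, 100), DL ~ U(0.18, 1),
  Caco-2 ~ U(0, 2); failing rows fail the OB gate decisively. Shared
  ingredients carry identical ADME values in every herb and are always
  generated as passing, so their status is consistent across herbs; the
  per-herb pass quota must cover the herb's shared count.
* PPI tables: planted hubs wired to their requested number of partners,
  an Erdős–Rényi background overlaid, all scores in [400, 1000] so
  default filtering keeps every edge.
* Expression: baseline means log-uniform over [10, 10⁴] arbitrary units
  (any positive range works, by scale invariance); model means multiply
  altered genes by `effect_fold` (up) or its inverse (down); treated
  means return rescued genes to baseline and hold non-rescued altered
  genes at the model mean (the simplest two-point alternative matching a
  binary rescued/not-rescued reading); samples put multiplicative
  log-normal(0, `noise_sd`) noise on group means, keeping values
  positive. Defaults: `effect_fold` 8, `noise_sd` 0.1, five samples per
  group. The effect size is set a factor of two above the alteration
  threshold so that planted genes are not generated on the decision
  boundary, where any noise model would make the planted label
  ill-defined; the study conditions constrain the effect only to be at
  or beyond threshold.
* Behavior: Y-maze sequences alternate at each step with probability
  `alternation_p`; NORT exploration splits a U(20, 60) s total by a
  Beta(20 m, 20 (1 − m)) fraction with mean m = DR/100; EPM closed-arm
  entries are Poisson.

What passing plant/recover tests show — and do not show: with zero noise
every call equals the planted truth exactly, and with noise the
recovered rescue fraction converges to the plant; this validates the
classification arithmetic, not the biology. Real RNA-seq has
gene-length and library-size structure, count noise with
mean–variance dependence, and batch effects, none of which the
log-normal-on-means model emulates; the pipeline is deliberately
unit-agnostic (pure fold thresholds, no dispersion estimation or
per-gene testing), so these features do not enter the computed
statistics either.

## Numerical choices and problem sizes

Ratios are computed in double precision with a symmetric pseudocount;
ties in every ranking break lexicographically, making all orderings
deterministic. The acceptance script runs the full pipeline on synthetic
inputs at the reported scale — 146 ingredient rows, 397 planted altered
genes in a 500-gene universe with five samples per group (25 replicate
seeds for the noisy mean), 100 seeds of a 40-protein hub-recovery
simulation, and 1000 replicates of the four-group null — sizes chosen so
the whole script completes in seconds while keeping the binomial and
type-I-error checks well-powered.

## Known limitations

* Name-based deduplication cannot merge synonymous compound names.
* Degree is the only centrality; no community structure or enrichment.
* Case-insensitive matching is not ortholog inference.
* The fold-threshold classification ignores within-group variance by
  design; it reproduces the published procedure, not a
  replicates-aware differential-expression model.
* Live database querying (TCMSP, STRING) is out of scope; the pipeline
  consumes exported tables only.
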