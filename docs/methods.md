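# Methods

This note documents the statistical procedures, the synthetic-data
model, the defaults and the numerical choices made where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Tissue-bias statistic

The bias of gene *g* toward target tissue *t* is the minimum over all
other atlas tissues *s* of `(x_gt + ε)/(x_gs + ε)`.  The minimum (not
mean or median) is deliberate and conservative: one permissive panel
tissue suffices to disqualify a gene.  Categories use inclusive lower
edges (<2, ≥2, ≥5, ≥10), so a ratio of exactly 10 is "highly biased".

* **Panel definition.** The panel is every atlas tissue except the
  target.  No germline exclusion is applied: when testis is the target,
  ovary remains in the panel.  This is prominent because it changes
  which genes clear the ≥10 bar.
* **Pseudocount ε.** Defaults to half the smallest positive intensity
  in the atlas, guarding division by zero.  With ε = 0 the statistic is
  exactly scale-invariant; with ε > 0 deviations are bounded by the ε
  perturbation.  The atlas is assumed pre-normalized between arrays;
  ε is exposed for sensitivity checks.

## Chromosomal representation

Representation ratio of set *S* on arm *a*:
`(|S∩a|/|S|) / (n_a/n_genome)`; 1.0 = genome average.  "Autosomes" is
the union {2L, 2R, 3L, 3R, 4}; chromosome 4 is retained.  Genes on Y or
unplaced scaffolds are dropped at load time (logged), fixing the
universe to the six-arm vocabulary.

Exact tests: hypergeometric lower/upper tails (both always reported;
consumers choose the direction, since depletion claims are one-sided
but the opposite tail is informative); Fisher's exact two-sided p uses
the point-probability rule (sum of all tables with fixed margins whose
probability does not exceed the observed one).  The category-table χ²
is Pearson's statistic on the 2×C table without continuity correction;
zero-margin categories are dropped with a warning, as is any expected
count below 5.  Both the 2×C form and a collapsed ≥10-vs-rest 2×2 (via
`fisher_2x2`) are available, since either contrast is defensible.

Multiple testing: Bonferroni within one analysis table (one family per
call — e.g. all arms of one representation analysis, or all
protein × timepoint correlation cells of one run); Benjamini–Hochberg
q-values within each differential-expression contrast.

## Time-course differential expression

1. log2 transform, then quantile normalization (columns forced onto the
   mean empirical distribution; ties receive the mean of the reference
   values they span).  This replaces the unstated external
   normalization protocol of the array study this emulates;
   distribution matching is the standard surrogate and the downstream
   statistics are rank- and ratio-based.
2. Per gene, a linear model over (day, stage) conditions pools the
   residual variance s² with d = n − c degrees of freedom.
3. Empirical-Bayes moderation: gene variances are modelled as scaled-F
   around a prior (d₀, s₀²), estimated from the marginal distribution
   of log s² by moment matching — `Var[log s²] = ψ′(d/2) + ψ′(d₀/2)`
   solved for d₀ by Newton inversion of the trigamma, then s₀² from the
   digamma mean relation.  When the observed spread of log s² does not
   exceed the sampling spread, d₀ = ∞ and every gene receives the
   pooled s₀² (the statistic becomes a pooled z).  With d₀ = 0 the
   ordinary pooled t is recovered; both limits are verified numerically
   in the tests.
4. Moderated t per later condition vs the earliest, p from the t
   distribution with d₀ + d df, q by Benjamini–Hochberg within each
   contrast.  "Up-regulated in testis development" = q < 0.1 **and**
   positive log2 fold change at ≥1 later timepoint — the directionality
   matters, as a gene significant only through down-regulation is not
   part of the activated cohort.

The global X-vs-autosome profile reports per-condition medians and
quartiles (medians with quartiles chosen over means, being robust to
the log-normal tail), the X − autosome median difference, a two-sided
Mann–Whitney p, and Bonferroni adjustment **across the conditions of
the profile** — a profile-level claim ("no difference at any
timepoint") is family-wise, so the adjusted p is the deciding number.

qRT-PCR: ΔCt = Ct_target − Ct_control per (gene, sample), ΔΔCt against
the designated reference sample, relative expression 2^(−ΔΔCt); the
reference sample is exactly 1 by construction and the statistic is
invariant to common Ct shifts.

## Chromatin association

Binding scores are continuous gene-level enrichments; thresholds are
per protein (the source datasets publish no canonical cutoffs) and
roles (silencing / activation) are input metadata, with defaults for
the eleven proteins most prominent in the underlying literature (H1,
H3K27me3, LamDm0, D1, Pc, esc, Sce → silencing; H3.3A, H3K4me3, DJun,
bcd → activation).

* **Universes are per-protein and pairwise-complete.**  Different
  source datasets assess different gene subsets; intersecting them all
  would discard most genes.  A gene missing a score is excluded from
  both numerator and denominator for that protein only.
* **Bound-gene enrichment** uses a single genome-wide baseline per
  protein (bound fraction among all assessed genes), against which the
  X-compartment and autosome-compartment set frequencies are both
  normalized.  Consequences: the size-weighted mean relative frequency
  of the full catalog over both compartments is exactly 1, and a set
  plus its complement reconstructs its compartment's overall relative
  frequency — these are the tested invariants.  An empty compartment
  yields a not-assessable flag rather than an error, so batch runs
  survive sparse sets.
* **Correlations** are Pearson on log2 fold changes vs raw scores
  (log2 is the default; the underlying study does not state log vs
  linear, and log is the scale on which array fold changes are
  approximately normal), two-sided p via the t transform, Bonferroni
  across the protein × timepoint series, cells with fewer than three
  shared genes omitted with a log entry.
* The **inverse-pattern flag** is true when significant silencing-role
  correlations are predominantly positive and significant
  activation-role correlations predominantly negative.

## Synthetic-data model

Baseline intensities are log-normal (ln-mean 6.0, ln-sd 1.2) — chosen
for the positivity and right skew of array signals; the pipeline
statistics are ratio- and rank-based, so the exact family is not
critical.  Multiplicative noise is log-normal with CV 0.2.  A single
root seed governs everything; each table draws from a substream derived
from (seed, table name), so regenerating one table never perturbs the
others, and identical configs give byte-identical outputs.

* **Planted tissue bias.**  Each gene is biased toward at most one
  tissue.  Default planted fractions: 8% of genes toward testis, 2%
  toward each of the 11 somatic/ovary panel tissues (testis hosts by
  far the largest specific-gene cohort in flies; roughly a third of
  genes carry some tissue bias).  Factors are drawn log-uniformly
  within three strata — 2–5× (weight 0.40), 5–10× (0.25), ≥10×
  (0.35, upper bound 1000×, since real testis-specific ratios reach
  hundreds-fold).
* **X depletion of high-bias genes.**  `x_highbias_depletion` (default
  0.5) multiplies the X-assignment probability of planted ≥10× genes,
  with the removed mass spread proportionally over the autosomes, so
  the parameter *is* the planted X representation ratio of those genes.
  `arm_proportions` (defaults approximating the euchromatic arm shares
  of the fly genome, X = 0.165) are interpreted as the **marginal**
  genome composition: arm proportions measured from a real genome
  already include whatever depletion shaped it, so non-high-bias genes
  receive a compensating X probability and the generated catalog
  matches the declared proportions for any depletion setting.  Without
  this, the planted ratio would be inflated by dilution of the genome
  baseline (≈0.5/(1 − f/2) for a planted ≥10× genome fraction f).
* **Activation trajectories.**  30% of genes are "activated": expected
  log2 expression rises linearly with day (slope uniform in 0.25–1.0
  log2/day) from the earliest condition; others are flat.  The default
  design is six conditions (days 4–7 feeding, 7 and 10 wandering,
  tracing larval testis development at 18°C) × 3 replicates.
* **Binding.**  Score = ρ·z + √(1−ρ²)·noise, where z standardizes the
  planted total up-regulation and ρ is +0.3 for silencing-role and
  −0.3 for activation-role proteins, multiplied by `x_attenuation`
  (default 0.3) for X-linked genes — emulating the weaker
  activation/repression switch observed on the X.  Thresholds sit at
  the 0.75 score quantile (the source thresholds are unpublished; a
  fixed quantile keeps bound fractions comparable across proteins).

What the generator does **not** emulate: probe-level effects, dye/
channel artifacts, spatial array structure, correlated gene modules,
multi-tissue bias, and between-array technical variation.  Passing
parameter-recovery tests therefore demonstrates correctness of the
statistics under the stated model, not robustness to every artifact of
real array data.

## Problem sizes and numerical choices

Simulation-based checks use genome-scale catalogs (13,000 genes, 100
seeded replicates) for depletion recovery, 1,000 replicates for null
calibration of enrichment p-values, 2,000-gene studies over 60–100
seeds for correlation recovery, and 60 seeds for the null X-vs-autosome
profile — sizes at which the sampling bands of the tested quantities
are a few times tighter than the asserted tolerances.  Exact tests are
compared with Fraction-arithmetic enumeration oracles over all
parameter combinations with universes up to 15 (tests) / 12
(acceptance script), where enumeration is itself exact.

Degenerate inputs: an arm equal to the whole genome gives both
hypergeometric tails = 1; zero-variance correlation inputs report
r = 0, p = 1; all-zero Fisher margins, empty panels, empty gene sets
and inconsistent counts raise usage errors naming the offending
quantity.

## Known limitations

* **Quantile normalization under global change.**  When a large gene
  cohort genuinely rises over the time course (30% activated under the
  defaults), distribution matching compresses the true fold changes —
  the measured fold change correlates ≈0.91 with the planted
  up-regulation under default noise.  This attenuates
  expression–binding correlations computed downstream of normalization
  by roughly that factor.  On synthetic data without planted
  between-array effects, correlation-recovery checks therefore compute
  fold changes on the log2 matrix directly; on real arrays the
  trade-off between removing technical variation and compressing
  genuine global shifts is inherent to the normalization choice.
* Multi-probe genes must be collapsed before loading (a per-gene median
  helper is provided); the choice of median is ours, as the source
  studies do not state a collapse rule.
* The bias statistic depends on the atlas panel composition; adding or
  removing panel tissues changes the minimal ratio and hence set
  membership.
* Binding-role labels are metadata, not inferred from the scores;
  misassigned roles invert the meaning of the inverse-pattern flag (the
  role-swap test quantifies exactly this sensitivity).
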