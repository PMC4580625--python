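# Methods

## Module derivation

A module is anchored on one marker gene and contains the `module_size`
(default 100) transcripts most positively correlated with it, by Pearson
correlation across the reference panel on the log2(RPM+1) scale as stored
(no re-normalization).  The marker is always its own top transcript: its
self-correlation is pinned to exactly 1.0 and it sorts first, so every
module contains its marker.  Genes with zero variance are excluded
(correlation undefined); negatively correlated transcripts are never used.
Ties at the rank boundary resolve to the lexicographically smaller gene id —
an arbitrary but documented rule that makes module membership deterministic.

Random gene sets are matched in size and count to the derived modules.  Each
set draws its genes uniformly without replacement *within* the set (a set
with duplicated genes would not have the fixed size the rest of the pipeline
assumes) and independently *across* sets, so genes recur freely between
sets.

## Survival screening

The per-sample module score is the median expression of the module genes
present in the cohort; at least 50% of the module must be present or the
module is skipped with reason "coverage" (the threshold is this package's
choice — there is no canonical value).  The cohort splits at the median
score with the lo group taking ties (`score <= median`), so with an even
number of distinct scores the split is equal and with heavy ties it can be
unbalanced; a one-sided split is skipped as "degenerate" rather than tested.

The log-rank statistic is the standard two-group O−E accumulation over
distinct event times with the hypergeometric variance, compared to
chi-square with 1 df.  It is implemented as a vectorized kernel over a
(samples × partitions) indicator matrix because the permutation nulls need
thousands of tests per cohort; the single-partition path is the same kernel
with one column.  Times tied between event and censoring follow the usual
convention that censored samples at time t remain at risk for the event at
t.  `direction` is the sign of (expected − observed) hi-group events: +1
when the hi stratum survives better.

Harrell's C is computed on the continuous module score (not the binary
partition), higher score treated as higher risk, score ties counting 0.5,
via lifelines.  Both the raw value and the oriented `max(C, 1−C)` are
reported with a flip flag, since a screening context cares about magnitude
of discrimination with the sign carried separately by `direction`.

Follow-up truncation sets times beyond the horizon (default 1825 days) to
the horizon with the event censored — administrative censoring that
equalizes follow-up across cohorts.

## Permutation calibration

Random sample partitions assign floor(n/2) samples to lo and the remainder
to hi, uniformly; with odd n the hi group takes the extra sample (the choice
is arbitrary; only "equal sized" is inherent).  Defaults are 1,000 sample
partitions and 526 random gene sets per cohort at thresholds 1e-3 and 5e-3;
expected-by-chance counts are n_tests × α.  BH FDR is computed within each
cohort's family of module tests, and the FDR attached to the largest
p-value under each threshold is summarized by its median across cohorts.

Counting "clusters" among significant modules builds a graph with an edge
when pairwise overlap exceeds 0.25 (strictly) and reports connected
components — a guard against double-counting near-identical modules.  The
theme filter retains a finding only when ≥2 significant modules share a
cluster or share a top annotation term; singletons are listed as
unsupported.

## Annotation and clustering

Module similarity is the fraction of shared genes (equal-size modules, so
the denominator is the module size).  Ward linkage runs on 1 − overlap.
The number of clusters under `k="auto"` maximizes the mean silhouette width
over cuts k = 2..30 of the Ward tree — a deterministic, dependency-light
substitute for model-based cluster-number selection; a fixed k is also
accepted.  Note `fcluster(maxclust)` can return fewer clusters than
requested when merge heights tie; cluster ids are always relabeled
contiguously from 1.

Enrichment is the upper-tail hypergeometric probability P(X ≥ k) with the
module and each annotation set intersected with the universe.  The universe
is the gene space of the reference panel used to build the modules — the
natural choice since those are the genes that *could* have entered a module.
BH runs within each reference collection over all (module, set) pairs.  The
per-cluster summary term is rule-derived: the members' most frequent top
term, ties broken by smallest FDR and then name — replacing what would
otherwise be a manual curation step.

## Genomic scans

Per-gene two-group comparisons use the Wilcoxon rank-sum test, two-sided:
exact null distribution when both groups have ≤10 values and no ties,
otherwise the normal approximation with midranks, tie-corrected variance
and continuity correction (cohort scans always take the asymptotic path,
vectorized across genes).  A constant gene reports p = 1.  No
multiple-testing correction is applied in scans; adjacent genes co-vary at
the chromosomal scale, so random partitions of the same samples serve as
the false-positive reference instead.  Genome order is the total order
(chromosome 1..22, X, Y; start ascending; gene id); "peaks" are maximal
runs of ≥ `min_run` (default 3) contiguous significant genes within a
chromosome — a formalization of visually identified significance peaks.

External BED input is 0-based half-open and converted to 1-based starts
internally; "chr" prefixes are stripped; strand is ignored (nothing in the
analysis uses it).

## Synthetic data

The generators state a world and keep it fixed:

* **Reference panel** — default 5 blocks × 100 genes + 1,000 background
  genes × 336 samples (the sample count mirrors a realistic purified-cell
  compendium).  Block genes load on a shared standard-normal factor with
  loading a = σ√(r/(1−r)) so same-block pairs have expected correlation
  r = 0.7; the marker's target correlation is (1+r)/2, strictly above the
  members', so it tops its own ranking.  Values sit on a baseline of 6.0
  log2 units with σ = 1.0 noise and clip at 0 to respect the log2(RPM+1)
  scale (clipping is rare at these defaults).
* **Tumor cohort** — infiltrate fraction f ~ Uniform(0,1) per sample; block
  genes gain 2.0 log2 units per unit f (linear on the log scale, keeping
  the median module score monotone in f); survival is exponential with
  hazard λ·exp(β·1[f > median f]), λ = 1/1000 per day, β default −1
  (protective high infiltrate); censoring is the minimum of an independent
  exponential (rate 1/2000 per day) and an administrative cutoff at 3000
  days, emulating date-of-last-visit censoring.  With these defaults about
  half the cohort experiences an observed death.
* **Copy number** — background Normal(0, 0.3) around copy-neutral; the
  low-infiltrate half carries a contiguous 30-gene region shifted down by
  0.8 copy-number units at a seed-chosen location; positions ascend along
  synthetic chromosomes (500 genes per chromosome, 10 kb spacing).

What the generator does **not** emulate: negative-binomial count noise,
tumor purity and deconvolution effects, correlated background structure,
subclonal copy-number mosaics, non-proportional hazards, or informative
censoring.  A green screen test therefore establishes that the machinery
recovers a planted linear-infiltrate, proportional-hazards signal — not
that it would survive every pathology of real RNA-seq cohorts.  All
generators are pure functions of (parameters, seed) and reruns are
bit-identical.

## Numerical and design notes

* Duplicate gene rows on input collapse to the highest-mean row (logged);
  the handling of duplicate symbols in public matrices is unspecified
  upstream, so the rule is this package's own.
* Expression/clinical sample mismatches are intersected, never imputed, with
  dropped counts logged.
* All randomness in a pipeline run derives from the single config seed via
  fixed offsets; artifacts carry a provenance header (config hash + seed,
  no timestamps) so fixed-seed reruns are byte-identical outside the log.
* The vectorized log-rank kernel returns p = 1 and χ² = 0 when the pooled
  variance is zero (e.g., identical groups); zero-event cohorts are a skip,
  not a statistic.
* Known limitations: the screen tests each module marginally (no
  multivariate adjustment, no Cox covariates); the silhouette-based cluster
  count can differ from model-based selection on the same data; the scan's
  peak definition is sensitive to `min_run` for narrow lesions.
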