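# immunomod

Immune gene-expression modules, median-split survival screening with
permutation nulls, and hi/lo genomic scans for tumor cohorts.

## The problem

Tumors differ widely in how strongly they are infiltrated by immune cells,
and in some tumor types that infiltrate predicts patient survival.  A robust
way to measure infiltrate from bulk RNA-seq is to anchor gene sets on
immune marker genes: for each marker (a CD antigen, cytokine, or
hematopoietic transcription factor), take the 100 transcripts most
positively correlated with it across a reference panel of purified immune
cells and whole blood.  Each such **module** tracks the abundance of a cell
type or immune program in a tumor sample.

`immunomod` implements that screening machinery end to end:

1. **Module building** — Pearson-correlate each marker against all genes of
   a reference panel; a module is the top 100 transcripts (the marker
   included, via its self-correlation of 1.0).  Size-matched random gene
   sets provide a gene-identity null.
2. **Survival screening** — score each tumor sample by the median
   expression of a module's genes, split the cohort at the cohort median
   (the "lo" half takes ties), and compare strata with the two-group
   log-rank test

   χ² = (Σⱼ (d₁ⱼ − dⱼ·n₁ⱼ/nⱼ))² / Σⱼ Vⱼ,  Vⱼ = dⱼ (n₁ⱼ/nⱼ)(1 − n₁ⱼ/nⱼ)(nⱼ − dⱼ)/(nⱼ − 1),

   accumulated over distinct event times j, with 1 df.  Harrell's
   concordance index of the continuous score and Kaplan–Meier curves
   complete the report; follow-up can be truncated at 5 years.
3. **Permutation calibration** — 1,000 random equal-sized sample partitions
   per cohort (≈1 expected below p = 1e-3 by chance) and 526 random gene
   sets (≈2.6 expected below 5e-3) give empirical false-positive counts to
   compare against the module tallies; BH FDRs per cohort are reported
   alongside.  Significant modules are de-duplicated by counting connected
   components under >25% gene overlap, and themes require support from ≥2
   modules sharing a cluster or annotation term.
4. **Annotation** — pairwise module overlap, Ward clustering of
   1 − overlap, and upper-tail hypergeometric enrichment against GMT
   reference collections with BH control (FDR < 0.05).
5. **Genomic scans** — per-gene two-sided Wilcoxon rank-sum comparisons of
   copy-number (or expression / protein) values between the hi and lo
   strata, ordered by genome position, with peak regions (runs of ≥3
   contiguous genes below p = 1e-3) and matched random-partition scans as
   the false-positive yardstick.

A synthetic-data generator with planted ground truth (coexpression blocks,
an infiltrate fraction driving an exponential proportional-hazards model,
and a contiguous copy-number deletion in low-infiltrate samples) makes every
stage testable without external data.

## Worked example

`examples/02_survival_screen.py` builds modules from a synthetic reference
panel and screens a 300-sample cohort in which high immune infiltrate halves
the death hazard (log hazard ratio −1):

```
cohort: 300 samples, 151 deaths observed
                chi_square    p  n_hi  n_lo  direction  concordance_oriented
module
block01_MK.mod     45.0408  0.0   150   150          1                0.6358
block02_MK.mod     46.0531  0.0   150   150          1                0.6391
block03_MK.mod     41.3073  0.0   150   150          1                0.6355
modules significant at p<1e-3: 3/3
```

Every planted module splits the cohort with a log-rank p far below 1e-3;
`direction = 1` means the module-hi half survives longer (the planted
protective effect), and the oriented concordance ≈ 0.64 quantifies the
score's discrimination.  On a null cohort (`examples/03_null_calibration.py`)
the same machinery is honest: 0 of 1,000 random sample partitions and 0 of
526 random gene sets reach p < 1e-3 against expectations of 1.0 and 0.53.

The other examples cover module construction (`01`), the copy-number scan
with its planted 30-gene deletion (`04`), and the one-configuration pipeline
that writes every artifact with a provenance header and is byte-identical
under a fixed seed (`05`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly simulated data, the screening procedure's null
calibration: the average number of random equal-sized sample partitions per
1,000 (over 20 null cohorts of 200 samples) whose log-rank test reaches
p < 1e-3.  The JSON output maps the target id to the computed value and the
number of partitions drawn.
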