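"""Synthetic reference panels, tumor cohorts, and copy-number tables.

The generators emulate the statistical structure the analysis relies on,
with planted ground truth recorded in a :class:`SyntheticTruth`:

* a reference panel of immune expression profiles in which each cell-type
  "block" of genes shares a latent per-sample factor, with one designated
  marker gene per block carrying the strongest loading;
* tumor cohorts in which a per-sample immune-infiltrate fraction drives both
  block-gene expression (linearly, on the log2 scale) and survival through an
  exponential proportional-hazards model with a binary hi/lo infiltrate
  covariate, under independent exponential plus administrative censoring;
* copy-number tables with a contiguous deletion carried by the
  low-infiltrate samples.

All generators are pure functions of (parameters, seed): reruns are
bit-identical.  Outputs satisfy every dataio validation invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    CHROMOSOME_ORDER,
    ClinicalTable,
    CNVTable,
    ExpressionMatrix,
    GenePositionTable,
    SyntheticTruth,
)

# Baseline log2(RPM+1) level around which genes fluctuate; high enough that
# clipping at zero is rare at the default noise level.
BASELINE_EXPRESSION = 6.0


def generate_reference_panel(
    n_blocks: int = 5,
    genes_per_block: int = 100,
    n_background_genes: int = 1000,
    n_samples: int = 336,
    within_block_corr: float = 0.7,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str], SyntheticTruth]:
    """Simulate a purified-immune-cell reference panel with coexpression blocks.

    Each block's genes load on a shared standard-normal per-sample factor with
    loading chosen so same-block gene pairs have expected Pearson correlation
    ``within_block_corr``; the block's marker gene carries a strictly higher
    loading so it tops its own correlation ranking.  Background genes are
    independent noise.  Values are shifted to a baseline and clipped at zero
    to respect the log2(RPM+1) scale.

    Returns the expression matrix, the marker gene list (one per block), and
    the planted truth.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if not 0 < within_block_corr < 1:
        raise ValueError("within_block_corr must lie in (0, 1)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)

    # loading a with corr(g1,g2) = a^2/(a^2+sd^2) = r  =>  a = sd*sqrt(r/(1-r))
    member_loading = noise_sd * np.sqrt(within_block_corr / (1 - within_block_corr))
    marker_corr = (1 + within_block_corr) / 2  # strictly higher than members
    marker_loading = noise_sd * np.sqrt(marker_corr / (1 - marker_corr))

    sample_ids = [f"REF{i + 1:04d}" for i in range(n_samples)]
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    cell_type_of_gene: dict[str, str] = {}
    marker_of_block: dict[str, str] = {}

    for b in range(n_blocks):
        block = f"block{b + 1:02d}"
        factor = rng.standard_normal(n_samples)
        marker = f"{block}_MK"
        marker_of_block[block] = marker
        for g in range(genes_per_block):
            if g == 0:
                gene, loading = marker, marker_loading
            else:
                gene, loading = f"{block}_G{g:03d}", member_loading
            noise = rng.normal(scale=noise_sd, size=n_samples)
            rows.append(BASELINE_EXPRESSION + loading * factor + noise)
            gene_ids.append(gene)
            cell_type_of_gene[gene] = block

    for g in range(n_background_genes):
        gene = f"BG_G{g + 1:05d}"
        rows.append(BASELINE_EXPRESSION + rng.normal(scale=noise_sd, size=n_samples))
        gene_ids.append(gene)
        cell_type_of_gene[gene] = "background"

    values = np.clip(np.vstack(rows), 0.0, None)
    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))
    truth = SyntheticTruth(
        seed=seed,
        cell_type_of_gene=cell_type_of_gene,
        marker_of_block=marker_of_block,
    )
    return expr, list(marker_of_block.values()), truth


def generate_tumor_cohort(
    n_samples: int,
    reference_truth: SyntheticTruth,
    beta: float = -1.0,
    baseline_hazard: float = 1 / 1000,
    censor_rate: float = 1 / 2000,
    admin_censor_days: float = 3000.0,
    seed: int = 0,
    infiltrate_gain: float = 2.0,
    noise_sd: float = 1.0,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Simulate a tumor cohort whose immune infiltrate modulates survival.

    Each sample draws an infiltrate fraction ``f ~ Uniform(0, 1)``.  Genes
    belonging to the reference panel's planted blocks gain expression linearly
    in ``f`` (``infiltrate_gain`` log2 units per unit of ``f``); background
    genes are pure noise.  Event times are exponential with hazard
    ``baseline_hazard * exp(beta * 1[f > median f])``; censoring is the
    minimum of an independent exponential (rate ``censor_rate``; 0 disables
    it) and administrative cutoff at ``admin_censor_days``.

    ``beta < 0`` makes high infiltrate protective (melanoma-like), ``beta >
    0`` deleterious (bladder-like), ``beta = 0`` the null.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    if admin_censor_days <= 0:
        raise ValueError("admin_censor_days must be positive")
    rng = np.random.default_rng(seed)

    sample_ids = [f"TUM{i + 1:04d}" for i in range(n_samples)]
    f = rng.uniform(size=n_samples)
    hi = f > np.median(f)

    genes = list(reference_truth.cell_type_of_gene)
    blocks = reference_truth.cell_type_of_gene
    values = np.empty((len(genes), n_samples))
    for i, gene in enumerate(genes):
        base = BASELINE_EXPRESSION + rng.normal(scale=noise_sd, size=n_samples)
        if blocks[gene] != "background":
            base = base + infiltrate_gain * f
        values[i] = base
    values = np.clip(values, 0.0, None)
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))

    hazard = baseline_hazard * np.exp(beta * hi.astype(float))
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=n_samples)
    else:
        censor_time = np.full(n_samples, np.inf)
    censor_time = np.minimum(censor_time, admin_censor_days)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    clinical = ClinicalTable(
        pd.DataFrame({"time": time, "event": event}, index=sample_ids)
    )

    truth = SyntheticTruth(
        seed=seed,
        cell_type_of_gene=dict(reference_truth.cell_type_of_gene),
        marker_of_block=dict(reference_truth.marker_of_block),
        infiltrate_fraction=dict(zip(sample_ids, f)),
        hazard_log_ratio=beta,
    )
    return expr, clinical, truth


def generate_cnv_profiles(
    cohort_truth: SyntheticTruth,
    n_genes: int = 2000,
    region_span: int = 30,
    loss_depth: float = 0.8,
    positions_per_chrom: int = 500,
    background_sd: float = 0.3,
    seed: int = 0,
) -> tuple[CNVTable, GenePositionTable, SyntheticTruth]:
    """Simulate a gene-level copy-number table with a planted focal deletion.

    Background values are Normal(0, ``background_sd``) around copy-neutral.
    The cohort's low-infiltrate samples carry a contiguous run of
    ``region_span`` genes shifted down by ``loss_depth`` (emulating a focal
    loss enriched in immune-poor tumors).  Gene positions are laid out in
    ascending order along synthetic chromosomes, ``positions_per_chrom``
    genes per chromosome.

    Returns the copy-number table, the position table, and a copy of the
    truth with ``deleted_region`` (gene index range in genome order) and
    ``deleted_samples`` filled in.
    """
    if region_span <= 0:
        raise ValueError("region_span must be positive")
    if region_span >= n_genes:
        raise ValueError("region_span must be smaller than n_genes")
    if not cohort_truth.infiltrate_fraction:
        raise ValueError("cohort_truth must carry infiltrate fractions")
    rng = np.random.default_rng(seed)

    samples = list(cohort_truth.infiltrate_fraction)
    deleted_samples = cohort_truth.lo_infiltrate_samples()
    gene_ids = [f"CN_G{i + 1:05d}" for i in range(n_genes)]
    values = rng.normal(scale=background_sd, size=(n_genes, len(samples)))

    region_start = int(rng.integers(0, n_genes - region_span + 1))
    region = (region_start, region_start + region_span)
    carrier = np.isin(samples, deleted_samples)
    values[region[0]:region[1], carrier] -= loss_depth

    cnv = CNVTable(pd.DataFrame(values, index=gene_ids, columns=samples))

    n_chroms = int(np.ceil(n_genes / positions_per_chrom))
    if n_chroms > len(CHROMOSOME_ORDER):
        raise ValueError("too many genes for the available chromosomes; "
                         "increase positions_per_chrom")
    chrom = [CHROMOSOME_ORDER[i // positions_per_chrom] for i in range(n_genes)]
    start = [(i % positions_per_chrom) * 10_000 + 1 for i in range(n_genes)]
    positions = GenePositionTable(
        pd.DataFrame({"chromosome": chrom, "start": start},
                     index=pd.Index(gene_ids, name="gene"))
    )

    truth = SyntheticTruth(
        seed=cohort_truth.seed,
        cell_type_of_gene=dict(cohort_truth.cell_type_of_gene),
        marker_of_block=dict(cohort_truth.marker_of_block),
        infiltrate_fraction=dict(cohort_truth.infiltrate_fraction),
        hazard_log_ratio=cohort_truth.hazard_log_ratio,
        deleted_region=region,
        deleted_samples=deleted_samples,
    )
    return cnv, positions, truth
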