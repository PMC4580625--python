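"""Gene-by-gene hi/lo comparisons along the genome.

Copy-number, expression, or protein values are compared between the hi and
lo strata of a partition with the two-sided Wilcoxon rank-sum test, gene by
gene, and the results ordered by (chromosome, start) for Manhattan-style
inspection.  No multiple-testing correction is applied; instead matched
random partitions of the same samples provide the false-positive yardstick
(adjacent genes co-vary at the chromosomal scale, so per-gene corrections
would be miscalibrated anyway).  Contiguous runs of significant genes are
summarized as peak regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .datatypes import (
    CNVTable,
    ExpressionMatrix,
    GenePositionTable,
    Partition,
)
from .calibration import random_sample_partitions


@dataclass
class GeneScanResult:
    """Per-gene two-group test results in genome order.

    ``table`` columns: chromosome, start, p, median_hi, median_lo, diff
    (lo - hi).  Genes without positions are kept at the end, flagged by
    ``positioned`` = False and excluded from Manhattan ordering.
    """

    table: pd.DataFrame
    n_hi: int
    n_lo: int

    @property
    def positioned(self) -> pd.DataFrame:
        return self.table[self.table["positioned"]]

    def significant(self, alpha: float = 1e-3) -> pd.DataFrame:
        return self.table[self.table["p"] < alpha]


@dataclass
class ScanComparison:
    """A module-partition scan next to matched random-partition scans."""

    module_scan: GeneScanResult
    random_scans: list[GeneScanResult]
    alpha: float
    module_count: int  # genes with p < alpha in the module scan
    random_counts: list[int]
    peaks: pd.DataFrame  # chromosome, start_gene, end_gene, n_genes, min_p


def wilcoxon_two_group(values_hi: np.ndarray, values_lo: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one gene.

    Uses the exact null distribution when both groups have <= 10 values and
    there are no ties; otherwise the normal approximation with midranks,
    tie-corrected variance and continuity correction.
    """
    hi = np.asarray(values_hi, dtype=float)
    lo = np.asarray(values_lo, dtype=float)
    if hi.size == 0 or lo.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([hi, lo])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (hi.size <= 10 and lo.size <= 10 and no_ties) \
        else "asymptotic"
    if np.ptp(pooled) == 0:
        return 1.0  # identical constant values: statistic at its null center
    res = mannwhitneyu(hi, lo, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(min(res.pvalue, 1.0))


def _scan_pvalues(values: np.ndarray, hi_mask: np.ndarray,
                  lo_mask: np.ndarray) -> np.ndarray:
    """Vectorized per-gene rank-sum p-values (asymptotic, tie-corrected)."""
    hi = values[:, hi_mask]
    lo = values[:, lo_mask]
    res = mannwhitneyu(hi, lo, alternative="two-sided", method="asymptotic",
                       use_continuity=True, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.ptp(values[:, hi_mask | lo_mask], axis=1) == 0
    p[constant] = 1.0
    return np.minimum(p, 1.0)


def scan_partition(
    table: CNVTable | ExpressionMatrix,
    partition: Partition,
    positions: GenePositionTable | None = None,
) -> GeneScanResult:
    """Per-gene Wilcoxon comparison of hi vs lo samples, genome-ordered.

    Group sizes in a cohort scan are large, so the asymptotic rank-sum path
    is used throughout; for tiny groups use :func:`wilcoxon_two_group`
    directly.  Genes lacking positions are scanned but flagged and sorted
    after the positioned genes.
    """
    data = table.data
    samples = [s for s in partition.labels.index if s in data.columns]
    if not samples:
        raise ValueError("no overlap between partition and table samples")
    labels = partition.labels.loc[samples]
    hi_samples = list(labels.index[labels == "hi"])
    lo_samples = list(labels.index[labels == "lo"])
    if not hi_samples or not lo_samples:
        raise ValueError("both hi and lo groups must be represented")

    values = data[samples].to_numpy()
    sample_idx = {s: i for i, s in enumerate(samples)}
    hi_mask = np.zeros(len(samples), dtype=bool)
    hi_mask[[sample_idx[s] for s in hi_samples]] = True
    lo_mask = ~hi_mask

    p = _scan_pvalues(values, hi_mask, lo_mask)
    median_hi = np.median(values[:, hi_mask], axis=1)
    median_lo = np.median(values[:, lo_mask], axis=1)

    out = pd.DataFrame({
        "p": p,
        "median_hi": median_hi,
        "median_lo": median_lo,
        "diff": median_lo - median_hi,
    }, index=data.index.rename("gene"))

    if positions is not None:
        pos = positions.data
        out = out.join(pos, how="left")
        out["positioned"] = out["chromosome"].notna()
    else:
        out["chromosome"] = pd.NA
        out["start"] = np.nan
        out["positioned"] = False

    if positions is not None:
        ordered = positions.genome_order()
        ordered_genes = [g for g in ordered.index if g in out.index]
        unpositioned = [g for g in out.index[~out["positioned"]]]
        out = out.loc[ordered_genes + sorted(unpositioned)]
    cols = ["chromosome", "start", "p", "median_hi", "median_lo", "diff",
            "positioned"]
    return GeneScanResult(table=out[cols], n_hi=len(hi_samples),
                          n_lo=len(lo_samples))


def find_peaks(scan: GeneScanResult, alpha: float = 1e-3,
               min_run: int = 3) -> pd.DataFrame:
    """Maximal runs of >= ``min_run`` contiguous significant positioned genes.

    Contiguity is in genome order within one chromosome.  Returns one row
    per peak with its bounding genes, gene count and minimum p-value.
    """
    df = scan.positioned
    peaks = []
    for chrom, sub in df.groupby("chromosome", sort=False, observed=True):
        sig = (sub["p"] < alpha).to_numpy()
        i = 0
        while i < len(sig):
            if sig[i]:
                j = i
                while j + 1 < len(sig) and sig[j + 1]:
                    j += 1
                if j - i + 1 >= min_run:
                    run = sub.iloc[i:j + 1]
                    peaks.append({
                        "chromosome": chrom,
                        "start_gene": run.index[0],
                        "end_gene": run.index[-1],
                        "start": int(run["start"].iloc[0]),
                        "end": int(run["start"].iloc[-1]),
                        "n_genes": j - i + 1,
                        "min_p": float(run["p"].min()),
                    })
                i = j + 1
            else:
                i += 1
    return pd.DataFrame(peaks, columns=["chromosome", "start_gene",
                                        "end_gene", "start", "end",
                                        "n_genes", "min_p"])


def compare_to_random(
    table: CNVTable | ExpressionMatrix,
    module_partition: Partition,
    positions: GenePositionTable,
    n_random: int = 1,
    seed: int = 0,
    alpha: float = 1e-3,
    min_run: int = 3,
) -> ScanComparison:
    """Scan the module partition and ``n_random`` matched random partitions.

    Reports per-scan counts of genes below ``alpha`` and the module scan's
    peak regions; the random counts estimate the false-positive load of a
    scan on this cohort.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    module_scan = scan_partition(table, module_partition, positions)
    samples = [s for s in module_partition.labels.index
               if s in table.data.columns]
    randoms = random_sample_partitions(samples, n_random, seed)
    random_scans = [scan_partition(table, p, positions) for p in randoms]
    return ScanComparison(
        module_scan=module_scan,
        random_scans=random_scans,
        alpha=alpha,
        module_count=int((module_scan.table["p"] < alpha).sum()),
        random_counts=[int((s.table["p"] < alpha).sum())
                       for s in random_scans],
        peaks=find_peaks(module_scan, alpha=alpha, min_run=min_run),
    )


def group_compare_features(
    table: CNVTable | ExpressionMatrix,
    partition: Partition,
    features: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Targeted hi/lo comparison for named genes or proteins.

    Returns a (results, missing) pair: per present feature the hi and lo
    medians and the two-sided Wilcoxon p; features absent from the table are
    listed in ``missing`` rather than raising — unless all are absent.
    """
    data = table.data
    present = [f for f in features if f in data.index]
    missing = [f for f in features if f not in data.index]
    if not present:
        raise ValueError("none of the requested features are in the table")
    samples = [s for s in partition.labels.index if s in data.columns]
    labels = partition.labels.loc[samples]
    hi = list(labels.index[labels == "hi"])
    lo = list(labels.index[labels == "lo"])
    rows = []
    for f in present:
        vh = data.loc[f, hi].to_numpy()
        vl = data.loc[f, lo].to_numpy()
        rows.append({
            "feature": f,
            "median_hi": float(np.median(vh)),
            "median_lo": float(np.median(vl)),
            "p": wilcoxon_two_group(vh, vl),
        })
    return pd.DataFrame(rows).set_index("feature"), missing
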