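"""Permutation nulls and significance tallies for the survival screen.

Two empirical nulls calibrate the module screen without parametric multiple-
testing assumptions: random equal-sized sample partitions (does *any* split
of this cohort predict survival?) and random gene sets matched in size to
the modules (does gene identity matter?).  Out of 1,000 random partitions
roughly n_perm * alpha splits are expected below a threshold alpha by
chance; counts are tallied at the screen's thresholds (1e-3 and 5e-3) and
compared with the module counts.  To avoid double-counting near-duplicate
modules, significant modules are also grouped into clusters connected by
>25% gene overlap, and themes are retained only when supported by at least
two significant modules sharing a cluster or a summary annotation term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .annotate import NO_TERM, AnnotationResult, ClusterAssignment
from .datatypes import ClinicalTable, Partition
from .survival import logrank_chi2_many

DEFAULT_THRESHOLDS: tuple[float, ...] = (1e-3, 5e-3)


@dataclass
class NullSummary:
    """Significance counts under permutation nulls, per cohort and overall.

    ``counts`` has one row per (cohort, source) with the number of tests
    falling below each threshold; ``expected`` holds n_tests * alpha for
    each row and threshold; ``mean_counts`` averages each source's counts
    across cohorts.
    """

    counts: pd.DataFrame  # index (cohort, source); columns: n_tests + thresholds
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    @property
    def expected(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.counts.index)
        for t in self.thresholds:
            out[t] = self.counts["n_tests"] * t
        return out

    @property
    def mean_counts(self) -> pd.DataFrame:
        return self.counts.groupby(level="source").mean()


@dataclass
class Table2Row:
    """Per-cohort summary of the screen against its permutation nulls."""

    cohort: str
    n_random_samples: dict[float, int]
    n_random_gene_sets: dict[float, int]
    n_modules: dict[float, int]
    n_clusters: dict[float, int]
    selected_top_modules: dict[float, list[str]]
    top_module_annotations: dict[float, list[str]]


def random_sample_partitions(samples: Sequence[str], n_perm: int,
                             seed: int = 0) -> list[Partition]:
    """Uniformly random equal-sized hi/lo partitions of a cohort.

    With odd n, hi takes the extra sample (ceil(n/2)); lo gets floor(n/2).
    Deterministic given the seed.
    """
    samples = list(samples)
    n = len(samples)
    if n < 4:
        raise ValueError("need >= 4 samples to partition")
    rng = np.random.default_rng(seed)
    n_lo = n // 2
    out = []
    for i in range(n_perm):
        perm = rng.permutation(n)
        labels = np.full(n, "hi", dtype=object)
        labels[perm[:n_lo]] = "lo"
        out.append(Partition(labels=pd.Series(labels, index=samples),
                             origin=f"random:{i}"))
    return out


def partition_matrix(partitions: Sequence[Partition]) -> np.ndarray:
    """Stack partitions into the (n_samples, n_partitions) hi indicator matrix
    consumed by the vectorized log-rank kernel."""
    return np.column_stack([
        (p.labels == "hi").to_numpy() for p in partitions
    ])


def logrank_null_pvalues(clinical: ClinicalTable, n_perm: int,
                         seed: int = 0) -> np.ndarray:
    """Log-rank p-values of ``n_perm`` random equal-sized partitions."""
    partitions = random_sample_partitions(clinical.sample_ids, n_perm, seed)
    hi = partition_matrix(partitions)
    _, p, _ = logrank_chi2_many(clinical.time.to_numpy(),
                                clinical.event.to_numpy(), hi)
    return p


def null_counts(
    screen_results: Mapping[str, Mapping[str, np.ndarray]],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> NullSummary:
    """Tally p-values below each threshold, per cohort and result source.

    ``screen_results`` maps cohort -> source -> p-value array, where source
    is e.g. ``"random_samples"``, ``"random_gene_sets"`` or ``"modules"``.
    """
    if not screen_results:
        raise ValueError("no screen results supplied")
    rows = []
    for cohort, by_source in screen_results.items():
        for source, pvals in by_source.items():
            pvals = np.asarray(pvals, dtype=float)
            pvals = pvals[np.isfinite(pvals)]
            row = {"cohort": cohort, "source": source, "n_tests": len(pvals)}
            for t in thresholds:
                row[t] = int((pvals < t).sum())
            rows.append(row)
    counts = pd.DataFrame(rows).set_index(["cohort", "source"])
    return NullSummary(counts=counts, thresholds=thresholds)


def count_significant_clusters(significant: Sequence[str],
                               overlap: pd.DataFrame,
                               threshold: float = 0.25) -> int:
    """Number of connected components among significant modules, with an edge
    whenever pairwise gene overlap exceeds the threshold (default >25%)."""
    significant = list(significant)
    missing = [m for m in significant if m not in overlap.index]
    if missing:
        raise KeyError(f"modules absent from overlap matrix: {missing[:5]}")
    if not significant:
        return 0
    sub = overlap.loc[significant, significant].to_numpy()
    adj = csr_matrix(sub > threshold)
    n_components, _ = connected_components(adj, directed=False)
    return int(n_components)


@dataclass
class ThemeReport:
    """Themes supported by >=2 significant modules, plus unsupported singletons."""

    cluster_themes: dict[int, list[str]] = field(default_factory=dict)
    term_themes: dict[str, list[str]] = field(default_factory=dict)
    unsupported: list[str] = field(default_factory=list)


def theme_filter(significant: Sequence[str], clusters: ClusterAssignment,
                 annotations: AnnotationResult) -> ThemeReport:
    """Retain biological themes with independent support.

    A theme survives when at least two significant modules share a cluster,
    or at least two significant modules (from any clusters) share a top
    annotation term.  Significant modules in no surviving theme are reported
    as unsupported.
    """
    significant = list(significant)
    by_cluster: dict[int, list[str]] = {}
    for m in significant:
        if m in clusters.labels.index:
            by_cluster.setdefault(int(clusters.labels[m]), []).append(m)
    cluster_themes = {c: ms for c, ms in by_cluster.items() if len(ms) >= 2}

    by_term: dict[str, set[str]] = {}
    for m in significant:
        if m in annotations.top_terms.index:
            for term in annotations.top_terms.loc[m]:
                if term != NO_TERM:
                    by_term.setdefault(term, set()).add(m)
    term_themes = {t: sorted(ms) for t, ms in by_term.items() if len(ms) >= 2}

    supported = set()
    for ms in cluster_themes.values():
        supported.update(ms)
    for ms in term_themes.values():
        supported.update(ms)
    unsupported = [m for m in significant if m not in supported]
    return ThemeReport(cluster_themes=cluster_themes, term_themes=term_themes,
                       unsupported=unsupported)


@dataclass
class CohortFDR:
    """BH FDR values per cohort and the cross-cohort medians at the cutoffs."""

    fdr: dict[str, pd.Series]  # cohort -> FDR aligned with its p-values
    at_cutoff: pd.DataFrame  # index cohort, columns cutoffs; NaN if no p below
    median_at_cutoff: pd.Series  # cutoff -> median FDR across cohorts


def bh_fdr_per_cohort(
    pvalues: Mapping[str, Sequence[float]],
    cutoffs: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> CohortFDR:
    """Benjamini-Hochberg step-up within each cohort's family of module tests.

    For each cutoff, reports the FDR attached to the largest p-value below
    that cutoff in each cohort, and the median of those FDRs across cohorts.
    """
    fdr: dict[str, pd.Series] = {}
    rows = {}
    for cohort, pv in pvalues.items():
        pv = pd.Series(np.asarray(pv, dtype=float))
        if pv.empty:
            raise ValueError(f"cohort {cohort!r} has no p-values")
        q = pd.Series(multipletests(pv.to_numpy(), method="fdr_bh")[1],
                      index=pv.index)
        fdr[cohort] = q
        at = {}
        for cut in cutoffs:
            below = pv[pv < cut]
            at[cut] = float(q[below.idxmax()]) if not below.empty else np.nan
        rows[cohort] = at
    at_cutoff = pd.DataFrame(rows).T
    at_cutoff.index.name = "cohort"
    return CohortFDR(fdr=fdr, at_cutoff=at_cutoff,
                     median_at_cutoff=at_cutoff.median())


def table2_row(
    cohort: str,
    module_pvalues: pd.Series,
    random_sample_pvalues: np.ndarray,
    random_gene_set_pvalues: np.ndarray,
    overlap: pd.DataFrame,
    clusters: ClusterAssignment | None = None,
    annotations: AnnotationResult | None = None,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    overlap_threshold: float = 0.25,
) -> Table2Row:
    """Assemble one cohort's summary row: significance counts for modules and
    both nulls, cluster counts among significant modules (>25% overlap rule),
    and a representative top module + annotation per threshold."""
    rs = np.asarray(random_sample_pvalues, dtype=float)
    rg = np.asarray(random_gene_set_pvalues, dtype=float)
    n_random_samples, n_random_gene_sets = {}, {}
    n_modules, n_clusters = {}, {}
    selected, top_ann = {}, {}
    for t in thresholds:
        n_random_samples[t] = int((rs < t).sum())
        n_random_gene_sets[t] = int((rg < t).sum())
        sig = module_pvalues[module_pvalues < t]
        n_modules[t] = len(sig)
        n_clusters[t] = count_significant_clusters(list(sig.index), overlap,
                                                   overlap_threshold)
        if sig.empty:
            selected[t], top_ann[t] = [], []
            continue
        if clusters is not None and annotations is not None:
            report = theme_filter(list(sig.index), clusters, annotations)
            reps, anns = [], []
            for ms in report.cluster_themes.values():
                best = sig[ms].idxmin()
                reps.append(best)
                cid = int(clusters.labels[best])
                term = annotations.cluster_terms.get(cid, NO_TERM)
                anns.append(term)
            selected[t] = reps
            top_ann[t] = anns
        else:
            selected[t] = [sig.idxmin()]
            top_ann[t] = []
    return Table2Row(
        cohort=cohort,
        n_random_samples=n_random_samples,
        n_random_gene_sets=n_random_gene_sets,
        n_modules=n_modules,
        n_clusters=n_clusters,
        selected_top_modules=selected,
        top_module_annotations=top_ann,
    )
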