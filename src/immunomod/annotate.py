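"""Module overlap, clustering, and hypergeometric functional annotation.

Modules built from similar markers (CD19 and CD20, say) share many genes, so
the collection is summarized by the fraction of pairwise gene overlap,
grouped by Ward agglomerative clustering on 1 - overlap, and annotated by
upper-tail hypergeometric enrichment against reference gene-set collections
with Benjamini-Hochberg control within each collection (FDR < 0.05).  Each
cluster receives a rule-derived summary term: the members' top term that
occurs most often in the cluster (ties broken by smallest FDR, then name).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneModule, GeneSetCollection, ModuleCollection

NO_TERM = "NS"  # no reference set at FDR < 0.05


@dataclass
class ClusterAssignment:
    """Cluster labels for every module plus the linkage needed to re-cut."""

    labels: pd.Series  # module name -> cluster id (contiguous from 1)
    n_clusters: int
    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        ids = np.sort(self.labels.unique())
        if not np.array_equal(ids, np.arange(1, self.n_clusters + 1)):
            raise ValueError("cluster ids must be contiguous from 1")

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


@dataclass
class AnnotationResult:
    """Long-format enrichment table plus per-module and per-cluster summaries."""

    table: pd.DataFrame  # module, collection, term, k, set_size, module_size, p, fdr
    top_terms: pd.DataFrame  # module x collection -> top term (or NS)
    cluster_terms: pd.Series  # cluster id -> summary term
    universe_size: int


def overlap_fraction(a: GeneModule, b: GeneModule) -> float:
    """|A ∩ B| / module size, for equal-size modules."""
    if len(a) != len(b):
        raise ValueError(
            f"modules {a.name!r} ({len(a)}) and {b.name!r} ({len(b)}) differ "
            "in size; the overlap fraction assumes equal sizes"
        )
    return len(a.member_set & b.member_set) / len(a)


def overlap_matrix(collection: ModuleCollection) -> pd.DataFrame:
    """Symmetric module x module overlap-fraction matrix with unit diagonal."""
    names = collection.names
    n = len(names)
    sets = [m.member_set for m in collection]
    size = len(collection.modules[0]) if n else 0
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if len(sets[j]) != size:
                raise ValueError("overlap matrix requires equal-size modules")
            values[i, j] = values[j, i] = len(sets[i] & sets[j]) / size
    out = pd.DataFrame(values, index=names, columns=names)
    assert np.allclose(out, out.T) and np.allclose(np.diag(out), 1.0)
    return out


def cluster_modules(overlap: pd.DataFrame, k: int | str = "auto",
                    k_max: int = 30) -> ClusterAssignment:
    """Ward clustering of modules on distance 1 - overlap.

    ``k="auto"`` scans 2..min(k_max, n-1) cuts of the Ward tree and keeps the
    one maximizing mean silhouette width on the precomputed distances;
    deterministic given the input.
    """
    n = len(overlap)
    dist = 1.0 - overlap.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = linkage(condensed, method="ward")

    if k == "auto":
        best_k, best_score = 2, -np.inf
        for kk in range(2, min(k_max, n - 1) + 1):
            labels = fcluster(link, t=kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(dist, labels, metric="precomputed")
            if score > best_score + 1e-12:
                best_k, best_score = kk, score
        k = best_k
    else:
        k = int(k)
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} modules available")

    raw = fcluster(link, t=k, criterion="maxclust")
    # relabel contiguously from 1 in order of first appearance
    remap: dict[int, int] = {}
    labels = np.array([remap.setdefault(c, len(remap) + 1) for c in raw])
    return ClusterAssignment(
        labels=pd.Series(labels, index=overlap.index),
        n_clusters=len(remap),
        linkage_matrix=link,
    )


def hypergeom_enrichment(module_genes: set, annotation_set: set,
                         universe: set) -> float:
    """Upper-tail hypergeometric P(X >= k) for the module/set gene overlap.

    Draws = |module ∩ universe|, successes = |set ∩ universe|, population =
    |universe|, observed k = |module ∩ set ∩ universe|.
    """
    if not universe:
        raise ValueError("universe is empty")
    module = set(module_genes) & universe
    ann = set(annotation_set) & universe
    k = len(module & ann)
    return float(hypergeom.sf(k - 1, len(universe), len(ann), len(module)))


def annotate_collection(
    collection: ModuleCollection,
    refs: list[GeneSetCollection],
    universe: set,
    clusters: ClusterAssignment | None = None,
    fdr_cutoff: float = 0.05,
) -> AnnotationResult:
    """Enrich every module against every reference set, with BH control
    applied within each reference collection over all (module, set) pairs.

    Per module and collection the top term is the minimum-FDR set passing
    ``fdr_cutoff`` (ties toward smaller p, then term name), else ``"NS"``.
    When a cluster assignment is given, each cluster's summary term is the
    most frequent top term among its member modules.
    """
    if not refs:
        raise ValueError("need at least one reference collection")
    universe = set(universe)
    records = []
    for ref in refs:
        coll_name = ref.source or "reference"
        for module in collection:
            mod_genes = module.member_set & universe
            for term, genes in ref:
                ann = set(genes) & universe
                k = len(mod_genes & ann)
                p = float(hypergeom.sf(k - 1, len(universe), len(ann),
                                       len(mod_genes)))
                records.append((module.name, coll_name, term, k, len(ann),
                                len(mod_genes), p))
    table = pd.DataFrame(records, columns=[
        "module", "collection", "term", "k", "set_size", "module_size", "p"])
    table["fdr"] = np.nan
    for coll_name, idx in table.groupby("collection").groups.items():
        table.loc[idx, "fdr"] = multipletests(
            table.loc[idx, "p"].to_numpy(), method="fdr_bh")[1]

    top = {}
    for (module, coll_name), sub in table.groupby(["module", "collection"]):
        passing = sub[sub["fdr"] < fdr_cutoff]
        if passing.empty:
            top[(module, coll_name)] = NO_TERM
        else:
            best = passing.sort_values(["fdr", "p", "term"]).iloc[0]
            top[(module, coll_name)] = best["term"]
    top_terms = pd.Series(top).unstack()
    top_terms.index.name = "module"

    cluster_terms = pd.Series(dtype=object)
    if clusters is not None:
        summary = {}
        fdr_of = table.set_index(["module", "collection", "term"])["fdr"]
        for cid in range(1, clusters.n_clusters + 1):
            votes: list[tuple[str, float]] = []
            for module in clusters.members(cid):
                if module not in top_terms.index:
                    continue
                for coll_name, term in top_terms.loc[module].items():
                    if term != NO_TERM:
                        votes.append((term, float(fdr_of[(module, coll_name,
                                                          term)])))
            if not votes:
                summary[cid] = NO_TERM
                continue
            df = pd.DataFrame(votes, columns=["term", "fdr"])
            tally = df.groupby("term").agg(count=("fdr", "size"),
                                           best=("fdr", "min"))
            tally = tally.sort_values(["count", "best"],
                                      ascending=[False, True],
                                      kind="stable")
            # deterministic tie-break on name
            lead = tally[(tally["count"] == tally["count"].iloc[0])
                         & (tally["best"] == tally["best"].iloc[0])]
            summary[cid] = sorted(lead.index)[0]
        cluster_terms = pd.Series(summary)
        cluster_terms.index.name = "cluster"

    return AnnotationResult(table=table, top_terms=top_terms,
                            cluster_terms=cluster_terms,
                            universe_size=len(universe))
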