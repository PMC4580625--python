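"""Derivation of marker-anchored transcript modules and random gene sets.

A module is the fixed-size set (default 100 genes, the marker included via
its self-correlation of 1.0) of transcripts most positively correlated with
a marker gene across a reference expression panel.  Correlations are plain
Pearson coefficients computed on the log2(RPM+1) values as stored.  Random
gene sets of matching size serve as the gene-identity permutation null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneModule, ModuleCollection

logger = logging.getLogger(__name__)


class DegenerateMarkerError(ValueError):
    """The marker gene has zero variance; correlations are undefined."""


def correlate_marker(expr: ExpressionMatrix, marker: str) -> pd.Series:
    """Pearson correlation of every gene with the marker, ranked descending.

    Zero-variance genes are excluded (their correlation is undefined).  Ties
    are broken by ascending gene id so the ranking is deterministic.
    """
    if marker not in expr.data.index:
        raise KeyError(f"marker {marker!r} not in expression matrix")
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to correlate")
    values = expr.data.to_numpy()
    m = expr.data.loc[marker].to_numpy()
    if m.std() == 0:
        raise DegenerateMarkerError(f"marker {marker!r} has zero variance")

    centered = values - values.mean(axis=1, keepdims=True)
    sds = centered.std(axis=1)
    mc = m - m.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ mc) / (values.shape[1] * sds * mc.std())
    keep = sds > 0
    ranked = pd.Series(r[keep], index=expr.data.index[keep])
    ranked.loc[marker] = 1.0  # exact self-correlation, immune to rounding
    # sort keys (last = primary): marker first, then r descending, then gene id
    genes = ranked.index.to_numpy()
    order = np.lexsort((genes, -ranked.to_numpy(), genes != marker))
    return ranked.iloc[order]


def build_module(expr: ExpressionMatrix, marker: str,
                 module_size: int = 100) -> GeneModule:
    """Build one module: the ``module_size`` genes best correlated with the
    marker (positively oriented ranking; the marker ranks first at r = 1).

    Ties at the rank boundary are resolved toward the lexicographically
    smaller gene id.
    """
    ranked = correlate_marker(expr, marker)
    if len(ranked) < module_size:
        raise ValueError(
            f"marker {marker!r}: only {len(ranked)} genes with defined "
            f"correlation; {module_size - len(ranked)} short of module size"
        )
    top = ranked.iloc[:module_size]
    return GeneModule(
        name=f"{marker}.mod",
        marker=marker,
        members=list(top.index),
        correlations=[float(v) for v in top.to_numpy()],
    )


def build_all_modules(expr: ExpressionMatrix, markers: list[str],
                      module_size: int = 100) -> ModuleCollection:
    """One module per marker present in the panel (``<MARKER>.mod`` naming).

    Markers absent from the panel are skipped with a warning; if none remain
    the collection would be empty and an error is raised instead.
    """
    if not markers:
        raise ValueError("marker list is empty")
    present = [m for m in markers if m in expr.data.index]
    missing = [m for m in markers if m not in expr.data.index]
    if missing:
        logger.warning("skipping %d markers absent from the panel: %s",
                       len(missing), missing[:5])
    if not present:
        raise ValueError("no markers present in the expression matrix")
    return ModuleCollection(
        modules=[build_module(expr, m, module_size) for m in present],
        provenance="derived",
    )


def random_gene_sets(universe: list[str], n_sets: int = 526,
                     set_size: int = 100, seed: int = 0) -> ModuleCollection:
    """Random gene sets matched in size to the derived modules.

    Each set draws ``set_size`` distinct genes uniformly from the universe;
    sets are drawn independently, so genes recur freely across sets.
    """
    if len(universe) < set_size:
        raise ValueError(
            f"universe of {len(universe)} genes cannot supply sets of {set_size}"
        )
    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(universe)
    modules = []
    for i in range(n_sets):
        members = rng.choice(universe_arr, size=set_size, replace=False)
        modules.append(GeneModule(
            name=f"random{i + 1:04d}",
            marker=f"random{i + 1:04d}",
            members=[str(g) for g in members],
            correlations=None,
        ))
    return ModuleCollection(modules=modules, provenance="random")


def member_union(collection: ModuleCollection) -> set[str]:
    """Union of member genes across the collection (reported, not asserted)."""
    out: set[str] = set()
    for module in collection:
        out.update(module.members)
    return out
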