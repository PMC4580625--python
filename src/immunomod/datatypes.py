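"""Shared domain types.

All tabular containers wrap :class:`pandas.DataFrame`/:class:`pandas.Series`
and validate their invariants on construction, so downstream stages can rely
on clean inputs: unique identifiers, finite values, and consistent shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CHROMOSOME_ORDER: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


class ValidationError(ValueError):
    """An input table violates a domain invariant."""


def _check_unique(values: Iterable[str], what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values on the log2(RPM+1) scale."""

    data: pd.DataFrame  # rows = genes, columns = samples

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("expression values must be finite")
        if (values < 0).any():
            raise ValidationError("expression values must be >= 0 (log2(RPM+1) scale)")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ClinicalTable:
    """Per-sample follow-up time (days) and event flag (1=death, 0=censored)."""

    data: pd.DataFrame  # index = sample ids, columns = time, event

    def __post_init__(self) -> None:
        required = {"time", "event"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        _check_unique(self.data.index, "sample ids")
        time = self.data["time"].to_numpy(dtype=float)
        if not np.isfinite(time).all() or (time < 0).any():
            raise ValidationError("follow-up times must be finite and >= 0")
        event = self.data["event"].to_numpy()
        if not np.isin(event, (0, 1)).all():
            raise ValidationError("event flags must be 0 or 1")
        self.data = self.data.assign(
            time=time, event=self.data["event"].astype(int)
        )[["time", "event"]]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. an annotation reference collection."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.sets.keys(), "gene-set names")
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass
class GenePositionTable:
    """1-based gene start positions on chromosomes 1..22, X, Y."""

    data: pd.DataFrame  # index = gene ids, columns = chromosome, start

    def __post_init__(self) -> None:
        required = {"chromosome", "start"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"position table missing columns: {sorted(missing)}")
        _check_unique(self.data.index, "gene ids")
        chroms = self.data["chromosome"].astype(str)
        bad = sorted(set(chroms) - set(CHROMOSOME_ORDER))
        if bad:
            raise ValidationError(f"unknown chromosome names: {bad}")
        start = self.data["start"].to_numpy(dtype=float)
        if (start < 1).any() or not np.isfinite(start).all():
            raise ValidationError("start positions must be >= 1 (1-based)")
        self.data = self.data.assign(
            chromosome=chroms, start=start.astype(np.int64)
        )[["chromosome", "start"]]

    def genome_order(self) -> pd.DataFrame:
        """Positions sorted by (chromosome rank, start, gene id)."""
        rank = {c: i for i, c in enumerate(CHROMOSOME_ORDER)}
        df = self.data.copy()
        df["_rank"] = df["chromosome"].map(rank)
        df["_gene"] = df.index
        df = df.sort_values(["_rank", "start", "_gene"])
        return df.drop(columns=["_rank", "_gene"])


@dataclass
class CNVTable:
    """GISTIC2-style gene-level copy-number estimates (0 ~ diploid-neutral)."""

    data: pd.DataFrame  # rows = genes, columns = samples

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValidationError("copy-number values must be finite")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class GeneModule:
    """A marker gene plus the fixed-size set of transcripts most positively
    correlated with it across a reference panel.

    ``correlations`` is absent (None) for random gene sets.
    """

    name: str
    marker: str
    members: list[str]
    correlations: list[float] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.members, f"members of module {self.name!r}")
        if self.correlations is not None:
            if len(self.correlations) != len(self.members):
                raise ValidationError(
                    f"module {self.name!r}: correlations/members length mismatch"
                )
            r = np.asarray(self.correlations, dtype=float)
            if not (np.diff(r) <= 1e-12).all():
                raise ValidationError(
                    f"module {self.name!r}: correlations must be sorted descending"
                )
            if self.marker not in self.members:
                raise ValidationError(
                    f"module {self.name!r}: marker must be a member (self-correlation 1)"
                )

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)


@dataclass
class ModuleCollection:
    """An ordered collection of modules (derived) or random gene sets."""

    modules: list[GeneModule]
    provenance: str = "derived"  # {"derived", "random"}

    def __post_init__(self) -> None:
        if self.provenance not in ("derived", "random"):
            raise ValidationError("provenance must be 'derived' or 'random'")
        _check_unique((m.name for m in self.modules), "module names")

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, name: str) -> GeneModule:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.modules]


@dataclass
class Partition:
    """A binary hi/lo labeling of a cohort's samples.

    ``labels`` maps sample id -> "hi" | "lo".  ``origin`` records whether the
    split came from a module score (``module:<name>``) or a random permutation
    (``random:<index>``).  ``score`` holds the per-sample score used for a
    module-based split.
    """

    labels: pd.Series
    origin: str
    score: pd.Series | None = None

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"hi", "lo"}
        if bad:
            raise ValidationError(f"partition labels must be hi/lo, got {sorted(bad)}")
        _check_unique(self.labels.index, "partition sample ids")

    @property
    def hi(self) -> list[str]:
        return list(self.labels.index[self.labels == "hi"])

    @property
    def lo(self) -> list[str]:
        return list(self.labels.index[self.labels == "lo"])

    @property
    def is_degenerate(self) -> bool:
        return len(self.hi) == 0 or len(self.lo) == 0


@dataclass
class SyntheticTruth:
    """Planted ground truth attached to every synthetic dataset.

    Records, for the reference panel, which block (if any) each gene belongs
    to and the block's designated marker; for tumor cohorts, the per-sample
    immune-infiltrate fraction and the planted log hazard ratio of the hi vs
    lo infiltrate halves; for copy-number tables, the deleted gene range and
    the carrier samples.
    """

    seed: int
    cell_type_of_gene: dict[str, str] = field(default_factory=dict)
    marker_of_block: dict[str, str] = field(default_factory=dict)
    infiltrate_fraction: dict[str, float] = field(default_factory=dict)
    hazard_log_ratio: float | None = None
    deleted_region: tuple[int, int] | None = None  # [start, stop) gene indices
    deleted_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for block, marker in self.marker_of_block.items():
            if self.cell_type_of_gene.get(marker) != block:
                raise ValidationError(
                    f"marker {marker!r} does not belong to its block {block!r}"
                )
        for s, f in self.infiltrate_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"infiltrate fraction of {s!r} outside [0,1]")
        if self.deleted_region is not None:
            lo, hi = self.deleted_region
            if lo < 0 or hi <= lo:
                raise ValidationError("deleted_region must be a non-empty index range")

    def hi_infiltrate_samples(self) -> list[str]:
        """Samples with infiltrate fraction above the cohort median."""
        f = pd.Series(self.infiltrate_fraction)
        return list(f.index[f > f.median()])

    def lo_infiltrate_samples(self) -> list[str]:
        f = pd.Series(self.infiltrate_fraction)
        return list(f.index[f <= f.median()])
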