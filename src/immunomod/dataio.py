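"""Readers and writers for the plain-text formats the pipeline touches.

Formats: tab-delimited gene x sample matrices, GCT 1.2, GMT gene sets, BED4
gene positions, and tab-delimited clinical / copy-number / protein tables.
External BED coordinates are 0-based half-open; internal positions are 1-based
starts.  "chr" prefixes are stripped on input.  All writers emit UTF-8 with LF
endings at full float precision, so write -> read round-trips are identities.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    CNVTable,
    ExpressionMatrix,
    GenePositionTable,
    GeneSetCollection,
    ValidationError,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def _read_matrix_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise FormatError(f"{path}: malformed table ({exc})") from exc
    return df


def _read_matrix_gct(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT header '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimensions line")
        n_genes, n_samples = (int(d) for d in dims)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_genes, n_samples):
        raise FormatError(
            f"{path}: GCT dims line says {(n_genes, n_samples)}, table is {df.shape}"
        )
    return df


def _coerce_numeric(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], cols[0]
        raise FormatError(
            f"{path}: non-numeric cell at gene {df.index[r]!r}, sample "
            f"{df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    if coerced.isna().to_numpy().any():
        raise FormatError(f"{path}: missing values are not supported")
    return coerced


def _collapse_duplicate_genes(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    # Duplicate gene rows: keep the row with the highest mean expression.
    if not df.index.has_duplicates:
        return df
    dups = df.index[df.index.duplicated()].unique().tolist()
    logger.warning("%s: collapsing %d duplicated gene ids (keeping highest-mean row): %s",
                   path, len(dups), dups[:5])
    means = df.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    keep_first = df.iloc[order]
    keep_first = keep_first[~keep_first.index.duplicated(keep="first")]
    return keep_first.loc[[g for g in dict.fromkeys(df.index)]]


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a gene x sample expression matrix (log2(RPM+1) scale).

    Parameters
    ----------
    path
        Input file; first column gene ids, remaining columns samples.
    dialect
        ``"tsv"`` for a plain tab-delimited matrix, ``"gct"`` for GCT 1.2
        (two-line header; Description column ignored).
    """
    path = Path(path)
    if dialect == "tsv":
        df = _read_matrix_tsv(path)
    elif dialect == "gct":
        df = _read_matrix_gct(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _coerce_numeric(df, path)
    df = _collapse_duplicate_genes(df, path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        expr.data.rename_axis("gene").to_csv(path, sep="\t", lineterminator="\n")
    elif dialect == "gct":
        n_genes, n_samples = expr.shape
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
            out = expr.data.copy()
            out.insert(0, "Description", "na")
            out.rename_axis("Name").to_csv(fh, sep="\t", lineterminator="\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, >=1 gene per line)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">=1 gene ({len(fields)} fields found)"
                )
            name = fields[0]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, genes in collection:
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a tab-delimited clinical table with columns sample, time, event."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing clinical columns {sorted(missing)}")
    df = df.set_index("sample")
    df.index = df.index.astype(str)
    return ClinicalTable(df[["time", "event"]])


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.rename_axis("sample").to_csv(path, sep="\t", lineterminator="\n")


def read_positions(path: str | Path) -> GenePositionTable:
    """Read a BED4 file into a 1-based gene position table.

    BED starts are 0-based half-open; internal starts are 1-based
    (``start_1based = bed_start + 1``).  "chr" prefixes are stripped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"],
                     usecols=[0, 1, 2, 3])
    chrom = df["chrom"].astype(str).str.removeprefix("chr")
    if (df["start"] < 0).any():
        raise ValidationError(f"{path}: negative BED start positions")
    out = pd.DataFrame(
        {"chromosome": chrom.to_numpy(), "start": df["start"].to_numpy() + 1},
        index=pd.Index(df["name"].astype(str), name="gene"),
    )
    return GenePositionTable(out)


def write_positions(positions: GenePositionTable, path: str | Path,
                    span: int = 1) -> None:
    """Write a position table as BED4 (start_0based = start - 1)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene, row in positions.data.iterrows():
            bed_start = int(row["start"]) - 1
            fh.write(f"chr{row['chromosome']}\t{bed_start}\t{bed_start + span}\t{gene}\n")


def read_cnv(path: str | Path) -> CNVTable:
    """Read a GISTIC2-style gene x sample copy-number table."""
    path = Path(path)
    df = _coerce_numeric(_read_matrix_tsv(path), path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CNVTable(df)


def write_cnv(cnv: CNVTable, path: str | Path) -> None:
    cnv.data.rename_axis("gene").to_csv(path, sep="\t", lineterminator="\n")


def intersect_samples(expr: ExpressionMatrix,
                      clinical: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both tables to their common samples (never impute).

    Keeps the expression matrix's sample order; logs how many samples each
    table loses.
    """
    common = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    n_expr_only = len(expr.sample_ids) - len(common)
    n_clin_only = len(clinical.sample_ids) - len(common)
    if n_expr_only or n_clin_only:
        logger.info(
            "sample intersection: %d common; dropped %d expression-only, "
            "%d clinical-only samples", len(common), n_expr_only, n_clin_only,
        )
    return (
        ExpressionMatrix(expr.data[common].copy()),
        clinical.subset(common),
    )
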