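"""End-to-end orchestration from a single configuration.

A :class:`RunConfig` either points at input files (expression, clinical,
markers, optional CNV/positions/annotation GMTs) or carries a ``simulate``
block of generator parameters.  ``run_screen_pipeline`` executes
build -> annotate -> screen -> calibrate and writes every artifact with a
provenance header (config hash + seed, no timestamps, so fixed-seed reruns
are byte-identical except for the log).  ``run_scan_pipeline`` adds the
genomic hi/lo scan for a chosen module partition.

One seed in the config determines all randomness; per-stage sub-seeds are
derived deterministically from it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import dataio
from .annotate import annotate_collection, cluster_modules, overlap_matrix
from .calibration import (
    DEFAULT_THRESHOLDS,
    bh_fdr_per_cohort,
    logrank_null_pvalues,
    null_counts,
    table2_row,
)
from .datatypes import GeneSetCollection, ModuleCollection
from .modules import build_all_modules, random_gene_sets
from .scan import compare_to_random
from .survival import median_partition, module_score, screen
from .synthdata import (
    generate_cnv_profiles,
    generate_reference_panel,
    generate_tumor_cohort,
)

logger = logging.getLogger(__name__)

# fixed offsets for deriving per-stage sub-seeds (kept below 2**31)
_SEED_SPAN = 10_000


class ConfigError(ValueError):
    """The run configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SimulateConfig:
    """Generator parameters for a fully synthetic run."""

    n_blocks: int = 5
    genes_per_block: int = 100
    n_background_genes: int = 1000
    n_ref_samples: int = 336
    within_block_corr: float = 0.7
    noise_sd: float = 1.0
    n_tumor_samples: int = 300
    beta: float = -1.0
    baseline_hazard: float = 1 / 1000
    censor_rate: float = 1 / 2000
    admin_censor_days: float = 3000.0
    cnv_n_genes: int = 2000
    cnv_region_span: int = 30
    cnv_loss_depth: float = 0.8
    cnv_positions_per_chrom: int = 500


@dataclass
class RunConfig:
    """Inputs, parameters and seed for one pipeline run."""

    outdir: str
    seed: int = 0
    expression: str | None = None
    clinical: str | None = None
    markers: str | None = None
    cnv: str | None = None
    positions: str | None = None
    annotation_gmts: list[str] = field(default_factory=list)
    simulate: SimulateConfig | None = None
    module_size: int = 100
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_permutations: int = 1000
    n_random_gene_sets: int = 526
    truncate: bool = False
    horizon_days: float = 1825.0
    overlap_threshold: float = 0.25
    n_random_scans: int = 1
    scan_module: str | None = None  # default: most significant module

    def __post_init__(self) -> None:
        if self.simulate is None:
            missing = [name for name in ("expression", "clinical", "markers")
                       if getattr(self, name) is None]
            if missing:
                raise ConfigError(
                    f"config needs either a simulate block or paths for: "
                    f"{missing}")
            for name in ("expression", "clinical", "markers", "cnv",
                         "positions"):
                path = getattr(self, name)
                if path is not None and not Path(path).exists():
                    raise ConfigError(f"{name} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            raw["simulate"] = SimulateConfig(**sim)
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # where outputs land does not change what they are
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode())
        return digest.hexdigest()[:12]


def _provenance(config: RunConfig) -> list[str]:
    return [f"# config_hash={config.config_hash()}", f"# seed={config.seed}"]


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig,
               index_label: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _provenance(config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", lineterminator="\n", index_label=index_label)


def read_pipeline_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a pipeline artifact, skipping its provenance header."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def simulate_to_dir(sim: SimulateConfig, outdir: str | Path, seed: int = 0):
    """Generate a full synthetic dataset and write it as plain-text files.

    Writes expression.tsv (tumor cohort), reference.tsv (panel),
    clinical.tsv, cnv.tsv, positions.bed, markers.txt and truth.json.
    Returns the in-memory objects for immediate use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref_expr, markers, ref_truth = generate_reference_panel(
        n_blocks=sim.n_blocks, genes_per_block=sim.genes_per_block,
        n_background_genes=sim.n_background_genes,
        n_samples=sim.n_ref_samples,
        within_block_corr=sim.within_block_corr, noise_sd=sim.noise_sd,
        seed=seed)
    tum_expr, clinical, cohort_truth = generate_tumor_cohort(
        n_samples=sim.n_tumor_samples, reference_truth=ref_truth,
        beta=sim.beta, baseline_hazard=sim.baseline_hazard,
        censor_rate=sim.censor_rate,
        admin_censor_days=sim.admin_censor_days, seed=seed + _SEED_SPAN)
    cnv, positions, truth = generate_cnv_profiles(
        cohort_truth, n_genes=sim.cnv_n_genes,
        region_span=sim.cnv_region_span, loss_depth=sim.cnv_loss_depth,
        positions_per_chrom=sim.cnv_positions_per_chrom,
        seed=seed + 2 * _SEED_SPAN)

    dataio.write_expression(ref_expr, outdir / "reference.tsv")
    dataio.write_expression(tum_expr, outdir / "expression.tsv")
    dataio.write_clinical(clinical, outdir / "clinical.tsv")
    dataio.write_cnv(cnv, outdir / "cnv.tsv")
    dataio.write_positions(positions, outdir / "positions.bed")
    (outdir / "markers.txt").write_text("\n".join(markers) + "\n",
                                        encoding="utf-8")
    truth_payload = {
        "seed": truth.seed,
        "marker_of_block": truth.marker_of_block,
        "hazard_log_ratio": truth.hazard_log_ratio,
        "deleted_region": list(truth.deleted_region),
        "n_deleted_samples": len(truth.deleted_samples),
        "infiltrate_model": "linear on log2 scale (explicit simplification)",
    }
    (outdir / "truth.json").write_text(
        json.dumps(truth_payload, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return ref_expr, markers, tum_expr, clinical, cnv, positions, truth


def _block_annotation_refs(truth) -> list[GeneSetCollection]:
    """Annotation reference derived from the planted blocks (simulate mode)."""
    sets: dict[str, list[str]] = {}
    for gene, block in truth.cell_type_of_gene.items():
        if block != "background":
            sets.setdefault(f"{block}_signature", []).append(gene)
    return [GeneSetCollection(sets=sets, source="planted_blocks")]


def run_screen_pipeline(config: RunConfig) -> Path:
    """Execute build -> annotate -> screen -> calibrate; return the outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("immunomod")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "load"
    written: list[Path] = []
    try:
        if config.simulate is not None:
            stage = "simulate"
            (ref_expr, markers, tum_expr, clinical, cnv, positions,
             truth) = simulate_to_dir(config.simulate, outdir / "data",
                                      seed=config.seed)
            refs = _block_annotation_refs(truth)
        else:
            ref_expr = dataio.read_expression(config.expression)
            clinical = dataio.read_clinical(config.clinical)
            markers = [m for m in Path(config.markers).read_text(
                encoding="utf-8").split() if m]
            tum_expr = ref_expr  # single-matrix mode: panel doubles as cohort
            refs = [dataio.read_gmt(p) for p in config.annotation_gmts]
        logger.info("stage load/simulate: %d genes x %d reference samples, "
                    "%d markers, %d cohort samples", *ref_expr.shape,
                    len(markers), len(clinical.sample_ids))

        stage = "build"
        collection = build_all_modules(ref_expr, markers, config.module_size)
        descriptions = {
            m.name: (f"marker={m.marker} min_r={min(m.correlations):.4f} "
                     f"median_r={float(np.median(m.correlations)):.4f}")
            for m in collection}
        dataio.write_gmt(
            GeneSetCollection({m.name: m.members for m in collection},
                              source="modules"),
            outdir / "modules.gmt", descriptions)
        written.append(outdir / "modules.gmt")
        logger.info("stage build: %d modules of size %d", len(collection),
                    config.module_size)

        stage = "annotate"
        overlap = overlap_matrix(collection)
        clusters = cluster_modules(overlap, k="auto",
                                   k_max=min(30, len(collection) - 1))
        universe = set(ref_expr.gene_ids)
        annotations = (annotate_collection(collection, refs, universe,
                                           clusters) if refs else None)
        _write_tsv(overlap, outdir / "overlap.tsv", config,
                   index_label="module")
        written.append(outdir / "overlap.tsv")
        cluster_df = clusters.labels.rename("cluster").to_frame()
        if annotations is not None:
            cluster_df = cluster_df.join(annotations.top_terms)
            cluster_df["summary_term"] = [
                annotations.cluster_terms.get(c, "NS")
                for c in cluster_df["cluster"]]
            _write_tsv(annotations.table.set_index("module"),
                       outdir / "annotations.tsv", config)
            written.append(outdir / "annotations.tsv")
        _write_tsv(cluster_df, outdir / "clusters.tsv", config,
                   index_label="module")
        written.append(outdir / "clusters.tsv")
        logger.info("stage annotate: %d clusters", clusters.n_clusters)

        stage = "screen"
        screen_matrix = screen(tum_expr, clinical, collection,
                               truncate=config.truncate,
                               horizon_days=config.horizon_days,
                               thresholds=config.thresholds)
        _write_tsv(screen_matrix.results, outdir / "screen.tsv", config)
        written.append(outdir / "screen.tsv")
        logger.info("stage screen: %d modules tested, counts %s",
                    len(screen_matrix.results),
                    screen_matrix.significant_counts)

        stage = "calibrate"
        rs_p = logrank_null_pvalues(clinical, config.n_permutations,
                                    seed=config.seed + 3 * _SEED_SPAN)
        rand_sets = random_gene_sets(tum_expr.gene_ids,
                                     n_sets=config.n_random_gene_sets,
                                     set_size=config.module_size,
                                     seed=config.seed + 4 * _SEED_SPAN)
        rg_screen = screen(tum_expr, clinical, rand_sets,
                           truncate=config.truncate,
                           horizon_days=config.horizon_days,
                           thresholds=config.thresholds)
        module_p = screen_matrix.results["p"].dropna()
        summary = null_counts({"cohort": {
            "random_samples": rs_p,
            "random_gene_sets": rg_screen.results["p"].dropna().to_numpy(),
            "modules": module_p.to_numpy(),
        }}, thresholds=config.thresholds)
        fdr = bh_fdr_per_cohort({"cohort": module_p.to_numpy()},
                                cutoffs=config.thresholds)
        counts = summary.counts.copy()
        counts.columns = ["n_tests"] + [f"n_p_lt_{t:g}"
                                        for t in config.thresholds]
        _write_tsv(counts.reset_index().set_index("cohort"),
                   outdir / "null_summary.tsv", config)
        written.append(outdir / "null_summary.tsv")

        row = table2_row(
            "cohort", module_p, rs_p,
            rg_screen.results["p"].dropna().to_numpy(), overlap, clusters,
            annotations, thresholds=config.thresholds,
            overlap_threshold=config.overlap_threshold)
        t2 = pd.DataFrame([{
            "cohort": row.cohort,
            **{f"random_samples_lt_{t:g}": row.n_random_samples[t]
               for t in config.thresholds},
            **{f"random_gene_sets_lt_{t:g}": row.n_random_gene_sets[t]
               for t in config.thresholds},
            **{f"modules_lt_{t:g}": row.n_modules[t]
               for t in config.thresholds},
            **{f"clusters_lt_{t:g}": row.n_clusters[t]
               for t in config.thresholds},
            **{f"top_modules_lt_{t:g}": ";".join(row.selected_top_modules[t])
               for t in config.thresholds},
            **{f"top_annotations_lt_{t:g}":
               ";".join(row.top_module_annotations[t])
               for t in config.thresholds},
            **{f"median_fdr_at_{t:g}": fdr.median_at_cutoff[t]
               for t in config.thresholds},
        }]).set_index("cohort")
        _write_tsv(t2, outdir / "table2.tsv", config)
        written.append(outdir / "table2.tsv")
        logger.info("stage calibrate: random-sample counts %s",
                    {t: int((rs_p < t).sum()) for t in config.thresholds})
    except Exception as exc:
        _mark_partial(written)
        raise StageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def _mark_partial(written: list[Path]) -> None:
    # outputs of the failing run keep a .partial suffix so a rerun cannot be
    # mistaken for a complete one
    for path in written:
        if path.exists():
            path.rename(path.with_suffix(path.suffix + ".partial"))


def run_scan_pipeline(config: RunConfig) -> Path:
    """Genomic hi/lo scan for a module partition of the simulated cohort.

    Requires a simulate block (CNV tables and positions come from it) or
    explicit ``cnv`` and ``positions`` paths plus screen outputs in
    ``outdir``.  The partition module defaults to the screen's most
    significant one.
    """
    outdir = Path(config.outdir)
    stage = "scan-load"
    try:
        screen_path = outdir / "screen.tsv"
        if not screen_path.exists():
            raise ConfigError("run_screen_pipeline must run first "
                              f"(missing {screen_path})")
        results = read_pipeline_tsv(screen_path)
        modules_gmt = dataio.read_gmt(outdir / "modules.gmt")
        if config.simulate is not None:
            data_dir = outdir / "data"
            expr = dataio.read_expression(data_dir / "expression.tsv")
            cnv = dataio.read_cnv(data_dir / "cnv.tsv")
            positions = dataio.read_positions(data_dir / "positions.bed")
        else:
            if config.cnv is None or config.positions is None:
                raise ConfigError("scan needs cnv and positions paths")
            expr = dataio.read_expression(config.expression)
            cnv = dataio.read_cnv(config.cnv)
            positions = dataio.read_positions(config.positions)

        module_name = config.scan_module or results["p"].idxmin()
        if module_name not in modules_gmt.sets:
            raise ConfigError(f"unknown scan module {module_name!r}")
        members = modules_gmt.sets[module_name]

        stage = "scan"
        from .datatypes import GeneModule
        module = GeneModule(name=module_name, marker=module_name,
                            members=members, correlations=None)
        ms = module_score(expr, module)
        common = [s for s in ms.scores.index if s in cnv.data.columns]
        partition = median_partition(ms.scores.loc[common],
                                     origin=f"module:{module_name}")
        comparison = compare_to_random(
            cnv, partition, positions, n_random=config.n_random_scans,
            seed=config.seed + 5 * _SEED_SPAN)
        scan_table = comparison.module_scan.table.drop(columns="positioned")
        _write_tsv(scan_table, outdir / "scan.tsv", config,
                   index_label="gene")
        _write_tsv(comparison.peaks, outdir / "peaks.tsv", config,
                   index_label="peak")
        counts = pd.DataFrame({
            "scan": ["module"] + [f"random{i + 1}" for i in
                                  range(len(comparison.random_counts))],
            f"n_p_lt_{comparison.alpha:g}": [comparison.module_count]
            + comparison.random_counts,
        }).set_index("scan")
        _write_tsv(counts, outdir / "scan_counts.tsv", config)
        logger.info("stage scan: module %s, %d significant genes, "
                    "random counts %s", module_name, comparison.module_count,
                    comparison.random_counts)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return outdir
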