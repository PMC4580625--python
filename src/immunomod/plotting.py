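"""Basic Kaplan-Meier and Manhattan plots for screen and scan results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .datatypes import CHROMOSOME_ORDER, ClinicalTable, Partition
from .scan import GeneScanResult
from .survival import km_estimate


def km_plot(clinical: ClinicalTable, partition: Partition,
            path: str | Path | None = None, title: str = ""):
    """Kaplan-Meier curves of the hi and lo strata."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, samples, color in (("hi", partition.hi, "tab:red"),
                                  ("lo", partition.lo, "tab:blue")):
        curve = km_estimate(clinical, samples)
        ax.step(curve.index, curve.to_numpy(), where="post",
                label=f"{group} (n={len(samples)})", color=color)
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def manhattan_plot(scan: GeneScanResult, alpha: float = 1e-3,
                   path: str | Path | None = None, title: str = ""):
    """-log10(p) of a genome scan, genes in (chromosome, start) order."""
    df = scan.positioned
    fig, ax = plt.subplots(figsize=(8, 3.5))
    x = np.arange(len(df))
    chroms = df["chromosome"].to_numpy()
    colors = {c: ("tab:gray" if i % 2 else "tab:blue")
              for i, c in enumerate(CHROMOSOME_ORDER)}
    ax.scatter(x, -np.log10(df["p"]), s=4,
               c=[colors[c] for c in chroms])
    ax.axhline(-np.log10(alpha), linestyle="--", color="k", linewidth=0.8)
    ticks, labels = [], []
    for chrom in dict.fromkeys(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        ticks.append(idx.mean())
        labels.append(chrom)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 p")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
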