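"""Diagnostic plots: knee plot, species-separation scatter, QC violins."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cells import KneeResult, QcReport

__all__ = ["knee_plot", "barnyard_plot", "qc_violin_plot"]


def knee_plot(rank_table: pd.DataFrame, knee: KneeResult | None = None,
              path: str | os.PathLike | None = None):
    """Cumulative read fraction vs barcode rank, with the knee marked."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(rank_table.index, rank_table["cumulative_fraction"], lw=1.5)
    if knee is not None:
        ax.axvline(knee.n_cells, color="red", lw=1,
                   label=f"knee: {knee.n_cells} cells ({knee.confidence_flag})")
        ax.legend()
    ax.set_xlabel("barcode rank (descending reads)")
    ax.set_ylabel("cumulative fraction of reads")
    ax.set_xscale("log")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def barnyard_plot(calls: pd.DataFrame, path: str | os.PathLike | None = None):
    """Species-separation scatter: UMIs of one species against the other."""
    species = calls.attrs.get("species")
    if species is None:
        umi_cols = [c for c in calls.columns if c.startswith("umis_")]
        species = tuple(c.removeprefix("umis_") for c in umi_cols[:2])
    a, b = species
    colors = {
        a: "tab:blue",
        b: "tab:red",
        "doublet": "purple",
        "below_threshold": "lightgrey",
    }
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, group in calls.groupby("label"):
        ax.scatter(group[f"umis_{a}"], group[f"umis_{b}"], s=8,
                   color=colors.get(label, "black"), label=label, alpha=0.7)
    ax.set_xlabel(f"{a} UMIs")
    ax.set_ylabel(f"{b} UMIs")
    ax.legend(markerscale=2, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def qc_violin_plot(qc: QcReport, path: str | os.PathLike | None = None):
    """Violin plots of genes and UMIs per cell (log scale)."""
    per_cell = qc.per_cell[qc.per_cell["total_umis"] > 0]
    fig, axes = plt.subplots(1, 2, figsize=(6, 4))
    for ax, column, title in zip(
        axes, ("genes_detected", "total_umis"), ("genes / cell", "UMIs / cell")
    ):
        values = per_cell[column].to_numpy(dtype=float)
        ax.violinplot(np.log10(values + 1), showmedians=True)
        ax.set_title(title)
        ax.set_ylabel("log10(count + 1)")
        ax.set_xticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
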