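"""Knee-point cell selection, filtering, and per-cell QC.

In a droplet run most beads see only ambient RNA; ordering barcodes by
descending read count and plotting the cumulative read fraction produces a
curve with an inflection point ("knee") that separates cell-containing
beads from ambient-only beads.  The knee here is the point of maximum
perpendicular distance between the (rank-normalized) cumulative curve and
the chord joining its endpoints, after light median smoothing — a
deterministic, parameter-light formulation of the visual inflection.

Downstream filters implement the standard exploratory rules: drop cells
with fewer than a profile-dependent number of UMIs (3500 for cell lines,
1000 for fly embryos, 300 for mouse brain), drop weakly detected genes,
keep the best n cells by a criterion, and compute per-cell QC including the
non-mitochondrial content percentage that flags broken cells (low values)
and bare nuclei (no mitochondrial expression at all).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import DgeMatrix, GeneAnnotation

__all__ = [
    "UMI_THRESHOLD_PROFILES",
    "KneeResult",
    "QcReport",
    "find_knee",
    "select_cells",
    "filter_min_umis",
    "filter_genes_min_count",
    "keep_best_cells",
    "cell_qc",
    "flag_low_mito_cells",
]

#: Default minimum-UMI thresholds per sample profile.
UMI_THRESHOLD_PROFILES = {
    "cell_line": 3500,
    "fly_embryo": 1000,
    "mouse_brain": 300,
}


@dataclass(frozen=True)
class KneeResult:
    """Inflection point of a barcode-rank curve.

    ``n_cells`` is the one-based rank of the knee; ``confidence_flag`` is
    ``weak`` when the curve is too close to a straight line for the knee to
    be meaningful (maximum chord distance below the cutoff).
    """

    n_cells: int
    cumulative_fraction_at_knee: float
    confidence_flag: str  # "sharp" | "weak"
    max_distance: float


def find_knee(
    rank_table: pd.DataFrame,
    smooth_window: int = 5,
    weak_threshold: float = 0.05,
) -> KneeResult:
    """Locate the knee of a barcode-rank cumulative curve.

    Ranks are normalized to [0, 1]; the cumulative fraction is median
    smoothed (centred window, identity on monotone stretches) and the knee
    is the rank maximizing the perpendicular distance to the chord from the
    first to the last point.
    """
    n = len(rank_table)
    if n < 3:
        raise ValueError(f"knee detection requires at least 3 barcodes, got {n}")
    y_raw = rank_table["cumulative_fraction"].to_numpy(dtype=float)
    y = (
        pd.Series(y_raw)
        .rolling(smooth_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    x = np.arange(1, n + 1, dtype=float) / n
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        distance = np.zeros(n)
    else:
        # signed cross product -> perpendicular distance to the chord
        distance = np.abs(chord[0] * (y - p0[1]) - chord[1] * (x - p0[0])) / norm
    idx = int(np.argmax(distance))
    max_d = float(distance[idx])
    return KneeResult(
        n_cells=idx + 1,
        cumulative_fraction_at_knee=float(y_raw[idx]),
        confidence_flag="sharp" if max_d >= weak_threshold else "weak",
        max_distance=max_d,
    )


def _top_barcodes(totals: pd.Series, n: int) -> pd.Index:
    """Top-n barcodes by total, ties broken lexicographically by barcode."""
    frame = totals.rename("total").rename_axis("barcode").reset_index()
    frame = frame.sort_values("barcode", kind="stable")
    frame = frame.sort_values("total", ascending=False, kind="stable")
    return pd.Index(frame["barcode"].iloc[:n])


def select_cells(
    dge: DgeMatrix,
    n: int | KneeResult,
    read_totals: pd.Series | None = None,
) -> DgeMatrix:
    """Keep the top-n barcodes, by read totals when available, else by UMIs.

    ``n`` may be a :class:`KneeResult` (its ``n_cells`` is used), matching
    the workflow of selecting as many barcodes as the knee indicates.
    Column order of the retained barcodes is preserved.
    """
    if isinstance(n, KneeResult):
        n = n.n_cells
    if n <= 0:
        raise ValueError(f"number of cells to select must be positive, got {n}")
    if n > dge.n_cells:
        raise ValueError(f"cannot select {n} cells from {dge.n_cells} barcodes")
    totals = dge.umis_per_cell() if read_totals is None else read_totals
    totals = totals.reindex(dge.cell_barcodes).fillna(0)
    keep = _top_barcodes(totals, n)
    kept_in_order = [b for b in dge.cell_barcodes if b in set(keep)]
    return dge.select_barcodes(kept_in_order)


def filter_min_umis(dge: DgeMatrix, min_umis: int) -> DgeMatrix:
    """Remove cells with *fewer than* ``min_umis`` total UMIs.

    The threshold is strict: a cell with exactly ``min_umis`` UMIs is kept.
    """
    if min_umis < 0:
        raise ValueError("min_umis must be >= 0")
    keep = dge.umis_per_cell() >= min_umis
    return DgeMatrix(dge.counts.loc[:, keep.to_numpy()])


def filter_genes_min_count(dge: DgeMatrix, min_total: int) -> DgeMatrix:
    """Remove genes whose total count across retained cells is below ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = dge.counts_per_gene() >= min_total
    return DgeMatrix(dge.counts.loc[keep.to_numpy(), :])


def keep_best_cells(dge: DgeMatrix, n: int, criterion: str = "umis") -> DgeMatrix:
    """Keep the best n cells by ``umis`` (total UMIs) or ``genes`` (genes detected)."""
    if not 1 <= n <= dge.n_cells:
        raise ValueError(f"n must be in [1, {dge.n_cells}], got {n}")
    if criterion == "umis":
        totals = dge.umis_per_cell()
    elif criterion == "genes":
        totals = dge.genes_per_cell()
    else:
        raise ValueError(f"unknown criterion {criterion!r} (expected 'umis' or 'genes')")
    keep = set(_top_barcodes(totals, n))
    return dge.select_barcodes([b for b in dge.cell_barcodes if b in keep])


@dataclass(frozen=True)
class QcReport:
    """Per-cell QC table and run-level summary.

    ``per_cell`` columns: barcode, total_umis, genes_detected,
    non_mito_percent (NaN for zero-UMI cells, which are excluded from the
    medians).  The summary reports median genes, UMIs and non-mito percent
    over cells with at least one UMI.
    """

    per_cell: pd.DataFrame
    summary: dict


def cell_qc(dge: DgeMatrix, annotation: GeneAnnotation) -> QcReport:
    """Per-cell totals, genes detected and non-mitochondrial content.

    The non-mitochondrial content of a cell is the sum of its UMIs minus
    the UMIs of mitochondrially encoded genes, divided by the total, as a
    percentage.  Every gene in the matrix must be annotated.
    """
    annotation.require_genes(dge.gene_ids)
    mito_flags = annotation.table.loc[dge.gene_ids, "is_mito"].to_numpy()
    totals = dge.umis_per_cell()
    mito = dge.counts.loc[mito_flags.astype(bool)].sum(axis=0)
    genes_detected = dge.genes_per_cell()
    with np.errstate(invalid="ignore", divide="ignore"):
        non_mito_percent = 100.0 * (totals - mito) / totals
    non_mito_percent = non_mito_percent.where(totals > 0, np.nan)
    per_cell = pd.DataFrame(
        {
            "barcode": dge.cell_barcodes,
            "total_umis": totals.to_numpy(),
            "mito_umis": mito.to_numpy(),
            "genes_detected": genes_detected.to_numpy(),
            "non_mito_percent": non_mito_percent.to_numpy(),
        }
    ).reset_index(drop=True)
    nonzero = per_cell[per_cell["total_umis"] > 0]
    summary = {
        "n_cells": int(len(per_cell)),
        "n_zero_umi_cells": int((per_cell["total_umis"] == 0).sum()),
        "median_genes": float(nonzero["genes_detected"].median()) if len(nonzero) else float("nan"),
        "median_umis": float(nonzero["total_umis"].median()) if len(nonzero) else float("nan"),
        "median_non_mito_percent": float(nonzero["non_mito_percent"].median())
        if len(nonzero)
        else float("nan"),
    }
    return QcReport(per_cell=per_cell, summary=summary)


def flag_low_mito_cells(qc: QcReport | pd.DataFrame, max_mito_percent: float = 1.0) -> set[str]:
    """Flag candidate nuclei: cells with under-represented mitochondrial RNA.

    A cell is flagged when its mitochondrial percentage
    (100 - non_mito_percent) is strictly below ``max_mito_percent``.
    Bare nuclei lack cytoplasm and hence mitochondria, so they show little
    or no mitochondrially encoded expression.
    """
    if not 0.0 <= max_mito_percent <= 100.0:
        raise ValueError("max_mito_percent must lie in [0, 100]")
    per_cell = qc.per_cell if isinstance(qc, QcReport) else qc
    valid = per_cell["non_mito_percent"].notna()
    mito_percent = 100.0 - per_cell["non_mito_percent"]
    flagged = per_cell.loc[valid & (mito_percent < max_mito_percent), "barcode"]
    return set(flagged)
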