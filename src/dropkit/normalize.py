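"""Normalization and cross-sample correlation.

ATPM (average transcripts per million) rescales every cell to the depth of
the deepest cell in the library: each gene's UMI count is divided by the
cell's total and multiplied by the maximum cell total.  Cross-sample
correlations are Pearson coefficients of log2(x + 1)-transformed profiles
over the intersection of genes captured in both libraries; single-cell
samples are aggregated to pseudobulk (per-gene sums over cells) before
comparison.  Bulk mRNA-seq comparators are expressed as RPKM using the
mean of a gene's isoform lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .dge import DgeMatrix, GeneAnnotation

__all__ = [
    "ExpressionProfile",
    "atpm_normalize",
    "pseudobulk",
    "correlate_profiles",
    "rpkm",
]

logger = logging.getLogger(__name__)

VALID_UNITS = ("counts", "ATPM", "RPKM", "log2p1")


@dataclass(frozen=True)
class ExpressionProfile:
    """A per-gene expression vector with its unit of measure."""

    values: pd.Series
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        values = self.values.astype(float)
        if not np.isfinite(values.to_numpy()).all():
            raise ValueError("profile values must be finite")
        if self.unit != "log2p1" and (values < 0).any():
            raise ValueError(f"{self.unit} values must be non-negative")
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate gene in profile: {dup!r}")
        object.__setattr__(self, "values", values.rename_axis("gene"))

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def __len__(self) -> int:
        return len(self.values)


def atpm_normalize(dge: DgeMatrix) -> pd.DataFrame:
    """Average transcripts per million: rescale cells to the deepest cell's total.

    Each cell's counts are divided by that cell's total UMIs and multiplied
    by the maximum total over cells, so every normalized column sums to the
    same depth.  Zero-total cells carry no information to rescale and are
    dropped with a warning.  A single-cell matrix is a fixed point.
    """
    totals = dge.umis_per_cell()
    nonzero = totals > 0
    if not nonzero.any():
        raise ValueError("cannot ATPM-normalize a matrix with no non-empty cells")
    dropped = int((~nonzero).sum())
    if dropped:
        logger.warning("atpm_normalize: dropping %d zero-total cells", dropped)
    counts = dge.counts.loc[:, nonzero.to_numpy()].astype(float)
    totals = totals[nonzero]
    max_total = float(totals.max())
    return counts.div(totals, axis=1) * max_total


def pseudobulk(dge: DgeMatrix) -> ExpressionProfile:
    """Aggregate a single-cell library to pseudobulk: per-gene sums over cells."""
    if dge.n_cells == 0:
        raise ValueError("pseudobulk requires at least one cell")
    return ExpressionProfile(dge.counts_per_gene().astype(float), unit="counts")


def _log2p1(values: np.ndarray) -> np.ndarray:
    return np.log2(values + 1.0)


def correlate_profiles(
    profile_x: ExpressionProfile,
    profile_y: ExpressionProfile,
) -> tuple[float, int]:
    """Pearson correlation of two profiles in log space.

    Profiles are subset to the intersection of genes present in both,
    transformed as log2(value + 1), and correlated.  Returns the
    coefficient and the number of common genes.
    """
    common = profile_x.gene_ids.intersection(profile_y.gene_ids)
    if len(common) == 0:
        raise ValueError("profiles share no genes; cannot correlate")
    x = _log2p1(profile_x.values.loc[common].to_numpy())
    y = _log2p1(profile_y.values.loc[common].to_numpy())
    if len(common) < 3:
        raise ValueError(f"need at least 3 common genes, got {len(common)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("a profile is constant over the common genes; correlation undefined")
    if np.array_equal(x, y):
        return 1.0, len(common)
    r = float(scipy.stats.pearsonr(x, y).statistic)
    return r, len(common)


def rpkm(
    bulk_counts: ExpressionProfile,
    annotation: GeneAnnotation,
    total_mapped_reads: int,
) -> ExpressionProfile:
    """Reads per kilobase per million mapped reads, with mean isoform lengths.

    value = count / (length_bp / 1000) / (total_mapped_reads / 1e6), where
    length_bp is the annotation's mean isoform length for the gene.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    lengths = annotation.mean_length(bulk_counts.gene_ids)
    values = (
        bulk_counts.values
        / (lengths / 1000.0)
        / (total_mapped_reads / 1_000_000.0)
    )
    return ExpressionProfile(values, unit="RPKM")
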