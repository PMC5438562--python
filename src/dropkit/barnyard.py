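"""Mixed-species (barnyard) analysis: species calls and doublet estimation.

In a barnyard design cells from two species (e.g. cultured human HEK and
mouse 3T3 cells) are mixed before encapsulation.  Because the reference
gene namespaces are disjoint, a barcode whose UMIs come almost exclusively
from one species is a confidently assignable singlet, while a substantial
mixture betrays a cross-species doublet.  Same-species doublets are
invisible to this readout; under random co-encapsulation the probability
that a doublet is cross-species is 2pq for mixing proportions (p, q), so
the total doublet rate is estimated as the observed cross-species doublet
fraction divided by 2pq.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dge import DgeMatrix, GeneAnnotation

__all__ = [
    "BarnyardSummary",
    "species_counts",
    "call_species",
    "summarize_barnyard",
]

LABEL_DOUBLET = "doublet"
LABEL_BELOW = "below_threshold"


def species_counts(dge: DgeMatrix, annotation: GeneAnnotation) -> pd.DataFrame:
    """Per-barcode UMI totals split by species.

    Returns one row per barcode with one column per species label (two
    species required); values are exact column sums over each species'
    gene set.
    """
    annotation.require_genes(dge.gene_ids)
    species = annotation.table.loc[dge.gene_ids, "species"].astype(str)
    labels = sorted(species.unique())
    if len(labels) != 2:
        raise ValueError(
            f"species_counts requires genes from exactly two species, got {labels}"
        )
    out = {}
    for label in labels:
        out[label] = dge.counts.loc[(species == label).to_numpy()].sum(axis=0)
    counts = pd.DataFrame(out)
    counts.index.name = "barcode"
    return counts


def call_species(
    counts: pd.DataFrame,
    purity_threshold: float = 0.90,
    min_umis: int = 3500,
) -> pd.DataFrame:
    """Classify each barcode as one species, a doublet, or below threshold.

    A barcode with fewer than ``min_umis`` total UMIs is ``below_threshold``
    (not classifiable).  Otherwise, if the majority species holds at least
    ``purity_threshold`` of the UMIs the barcode is called as that species
    — the boundary is inclusive, so exactly 90 out of 100 UMIs declares the
    cell at the default threshold — and anything less pure is a doublet.
    """
    if not 0.5 <= purity_threshold <= 1.0:
        raise ValueError("purity_threshold must lie in [0.5, 1]")
    if min_umis < 0:
        raise ValueError("min_umis must be >= 0")
    if counts.shape[1] != 2:
        raise ValueError("call_species expects two species-count columns")
    label_a, label_b = counts.columns
    a = counts[label_a].to_numpy(dtype=np.int64)
    b = counts[label_b].to_numpy(dtype=np.int64)
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(total > 0, np.maximum(a, b) / total, np.nan)
    majority = np.where(a >= b, label_a, label_b)
    label = np.where(
        total < min_umis,
        LABEL_BELOW,
        np.where(purity >= purity_threshold, majority, LABEL_DOUBLET),
    )
    calls = pd.DataFrame(
        {
            "barcode": counts.index.astype(str),
            f"umis_{label_a}": a,
            f"umis_{label_b}": b,
            "total_umis": total,
            "purity": purity,
            "label": label,
        }
    ).reset_index(drop=True)
    calls.attrs["species"] = (label_a, label_b)
    return calls


@dataclass(frozen=True)
class BarnyardSummary:
    """Label counts and the extrapolated total doublet rate.

    ``cross_species_doublet_fraction`` is doublets / (doublets + singlets)
    over barcodes passing the UMI threshold;
    ``extrapolated_total_doublet_rate`` divides it by 2pq to account for
    invisible same-species doublets.
    """

    label_counts: dict[str, int]
    cross_species_doublet_fraction: float
    extrapolated_total_doublet_rate: float
    mixing_proportions: tuple[float, float]

    @property
    def n_calls(self) -> int:
        return sum(self.label_counts.values())

    def to_dict(self) -> dict:
        return {
            "label_counts": dict(self.label_counts),
            "cross_species_doublet_fraction": self.cross_species_doublet_fraction,
            "extrapolated_total_doublet_rate": self.extrapolated_total_doublet_rate,
            "mixing_proportions": list(self.mixing_proportions),
        }


def summarize_barnyard(
    calls: pd.DataFrame,
    mixing_proportions: tuple[float, float] = (0.5, 0.5),
) -> BarnyardSummary:
    """Summarize species calls and extrapolate the total doublet rate.

    Ambient-derived cross-species UMIs are not subtracted before
    classification, which can bias the doublet fraction upward when
    ambient contamination is high; the summary reports raw counts.
    """
    p, q = mixing_proportions
    if not (0 <= p <= 1 and 0 <= q <= 1) or abs(p + q - 1.0) > 1e-6:
        raise ValueError("mixing proportions must be non-negative and sum to 1")
    labels = calls["label"]
    label_counts = labels.value_counts().to_dict()
    n_classified = int((labels != LABEL_BELOW).sum())
    if n_classified == 0:
        raise ValueError("no calls pass the UMI threshold; nothing to summarize")
    n_doublets = int((labels == LABEL_DOUBLET).sum())
    cross_fraction = n_doublets / n_classified
    if n_doublets == 0:
        total_rate = 0.0
    else:
        if p * q == 0:
            raise ValueError(
                "observed cross-species doublets with a single-species mix; "
                "check the mixing proportions"
            )
        total_rate = cross_fraction / (2.0 * p * q)
    return BarnyardSummary(
        label_counts={str(k): int(v) for k, v in label_counts.items()},
        cross_species_doublet_fraction=float(cross_fraction),
        extrapolated_total_doublet_rate=float(total_rate),
        mixing_proportions=(float(p), float(q)),
    )
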