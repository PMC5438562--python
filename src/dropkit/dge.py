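"""Core data types and digital counting.

The central object is the digital gene expression (DGE) matrix: genes by
cell barcodes, each entry the number of *distinct* UMIs observed for that
(gene, barcode) pair.  Counting distinct UMIs collapses PCR duplicates and
digitally counts mRNA molecules.  UMI collapse is by exact string match;
edit-distance merging of near-identical UMIs is deliberately out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BARCODE_LENGTH",
    "UMI_LENGTH",
    "ParsedRead1",
    "DgeMatrix",
    "GeneAnnotation",
    "parse_read1",
    "count_umis",
    "barcode_rank",
    "barcode_base_composition",
]

logger = logging.getLogger(__name__)

BARCODE_LENGTH = 12
UMI_LENGTH = 8
READ1_LENGTH = BARCODE_LENGTH + UMI_LENGTH

_ACGTN = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class ParsedRead1:
    """Cell barcode and UMI parsed from a read-1 sequence.

    ``valid`` is False when the sequence contains an ambiguous base (N);
    such reads are dropped from counting rather than guessed at.
    """

    barcode: str
    umi: str
    valid: bool


def parse_read1(sequence: str) -> ParsedRead1:
    """Split a 20 bp read-1 sequence into cell barcode and UMI.

    Bases 1-12 are the cell barcode, bases 13-20 the UMI.
    """
    if len(sequence) != READ1_LENGTH:
        raise ValueError(
            f"read 1 must be exactly {READ1_LENGTH} bp "
            f"({BARCODE_LENGTH} bp barcode + {UMI_LENGTH} bp UMI); got {len(sequence)} bp"
        )
    if not _ACGTN.match(sequence):
        raise ValueError(f"read 1 contains characters outside ACGTN: {sequence!r}")
    return ParsedRead1(
        barcode=sequence[:BARCODE_LENGTH],
        umi=sequence[BARCODE_LENGTH:],
        valid="N" not in sequence,
    )


class DgeMatrix:
    """Digital gene expression matrix: genes x cell barcodes, distinct-UMI counts.

    Wraps a dense integer DataFrame (genes on the index, barcodes on the
    columns).  Entries are non-negative integers; gene and barcode
    identifiers are unique.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.copy()
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValueError(f"duplicate cell barcode: {dup!r}")
        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.allclose(values, np.round(values), atol=0):
                    raise ValueError("DGE counts must be integers")
                counts = counts.astype(np.int64)
                values = counts.to_numpy()
            if (values < 0).any():
                raise ValueError("DGE counts must be non-negative")
        counts = counts.astype(np.int64)
        counts.index = counts.index.astype(str)
        counts.index.name = "gene"
        counts.columns = counts.columns.astype(str)
        counts.columns.name = "barcode"
        self.counts = counts

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_barcodes(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def umis_per_cell(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def counts_per_gene(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def genes_per_cell(self) -> pd.Series:
        return (self.counts > 0).sum(axis=0)

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def select_barcodes(self, barcodes: Sequence[str]) -> "DgeMatrix":
        return DgeMatrix(self.counts.loc[:, list(barcodes)])

    def select_genes(self, genes: Sequence[str]) -> "DgeMatrix":
        return DgeMatrix(self.counts.loc[list(genes), :])

    def equals(self, other: "DgeMatrix") -> bool:
        return self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"DgeMatrix({self.n_genes} genes x {self.n_cells} barcodes, {self.total()} UMIs)"


class GeneAnnotation:
    """Per-gene metadata: species tag, mitochondrial flag, mean isoform length.

    The mean isoform length (bp, averaged over a gene's isoforms) feeds RPKM
    conversion of bulk comparators; the species tag drives barnyard
    splitting; the mitochondrial flag drives the non-mitochondrial-content
    QC statistic.
    """

    REQUIRED = ("species", "is_mito", "mean_isoform_length")

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "gene_id" in table.columns:
            table = table.set_index("gene_id")
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"annotation is missing columns: {missing}")
        if table.index.has_duplicates:
            dup = table.index[table.index.duplicated()][0]
            raise ValueError(f"duplicate gene in annotation: {dup!r}")
        table.index = table.index.astype(str)
        table.index.name = "gene_id"
        table["is_mito"] = table["is_mito"].astype(bool)
        table["mean_isoform_length"] = table["mean_isoform_length"].astype(float)
        lengths = table["mean_isoform_length"]
        bad = lengths[lengths.notna() & (lengths <= 0)]
        if len(bad):
            raise ValueError(f"non-positive isoform length for gene {bad.index[0]!r}")
        self.table = table

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def species_labels(self) -> list[str]:
        return sorted(self.table["species"].astype(str).unique())

    def require_genes(self, genes: Iterable[str]) -> None:
        missing = pd.Index(genes).difference(self.table.index)
        if len(missing):
            raise KeyError(f"gene not in annotation: {missing[0]!r}")

    def mito_genes(self) -> pd.Index:
        return self.table.index[self.table["is_mito"]]

    def genes_of_species(self, species: str) -> pd.Index:
        return self.table.index[self.table["species"].astype(str) == species]

    def mean_length(self, genes: Sequence[str]) -> pd.Series:
        self.require_genes(genes)
        lengths = self.table.loc[list(genes), "mean_isoform_length"]
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()][0]
            raise ValueError(f"missing mean isoform length for gene {missing!r}")
        return lengths

    def __repr__(self) -> str:
        return f"GeneAnnotation({len(self.table)} genes, species={self.species_labels})"


def _valid_tag_mask(reads: pd.DataFrame) -> tuple[np.ndarray, dict[str, int]]:
    bc = reads["barcode"].astype(str)
    umi = reads["umi"].astype(str)
    ok_len = (bc.str.len() == BARCODE_LENGTH) & (umi.str.len() == UMI_LENGTH)
    ok_alpha = bc.str.fullmatch(r"[ACGT]+").fillna(False) & umi.str.fullmatch(
        r"[ACGT]+"
    ).fillna(False)
    mask = (ok_len & ok_alpha).to_numpy()
    stats = {
        "bad_length": int((~ok_len).sum()),
        "bad_alphabet": int((ok_len & ~ok_alpha).sum()),
    }
    return mask, stats


def count_umis(reads: pd.DataFrame, *, assume_valid: bool = False) -> DgeMatrix:
    """Collapse PCR duplicates and count distinct UMIs per (gene, barcode).

    Each matrix entry is the number of distinct UMI strings seen with that
    barcode and gene (exact-match collapse).  Reads without a gene label are
    ignored; malformed reads (wrong tag length, non-ACGT characters
    including N) are dropped and tallied in the log.  ``assume_valid``
    skips the validity scan for trusted inputs such as simulator output.
    """
    if reads is None or len(reads) == 0:
        return DgeMatrix(pd.DataFrame(np.empty((0, 0), dtype=np.int64)))
    barcode, umi, gene = reads["barcode"], reads["umi"], reads["gene"]
    gene_present = gene.notna()
    if not isinstance(gene.dtype, pd.CategoricalDtype) and (
        gene.dtype == object or pd.api.types.is_string_dtype(gene)
    ):
        gene_present &= gene.astype(str).str.len() > 0
    keep = gene_present.to_numpy()
    n_unassigned = int((~keep).sum())
    if not assume_valid:
        mask, stats = _valid_tag_mask(reads)
        n_bad = int((keep & ~mask).sum())
        if n_bad or n_unassigned:
            logger.info(
                "count_umis: dropped %d malformed reads (%d bad length, %d bad alphabet) "
                "and ignored %d reads without a gene label",
                n_bad, stats["bad_length"], stats["bad_alphabet"], n_unassigned,
            )
        keep &= mask
    if not keep.any():
        return DgeMatrix(pd.DataFrame(np.empty((0, 0), dtype=np.int64)))
    counts = _distinct_umi_counts(barcode, umi, gene, keep)
    return DgeMatrix(counts)


def _int_codes(column: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(column.dtype, pd.CategoricalDtype):
        return (
            column.cat.codes.to_numpy().astype(np.int64),
            column.cat.categories.to_numpy().astype(str),
        )
    codes, uniques = pd.factorize(column.to_numpy())
    return codes.astype(np.int64), np.asarray(uniques).astype(str)


def _distinct_umi_counts(
    barcode: pd.Series, umi: pd.Series, gene: pd.Series, keep: np.ndarray
) -> pd.DataFrame:
    """Distinct-(barcode, UMI, gene) counts per (gene, barcode), as a dense frame.

    Triples are deduplicated by integer-encoding the three columns into a
    single key; falls back to a pandas groupby when the key would overflow.
    """
    b_codes, b_names = _int_codes(barcode)
    g_codes, g_names = _int_codes(gene)
    u_codes, _ = pd.factorize(umi.to_numpy())
    b_codes, g_codes = b_codes[keep], g_codes[keep]
    u_codes = u_codes[keep].astype(np.int64)
    nb, ng, nu = len(b_names), len(g_names), int(u_codes.max()) + 1
    if float(nb) * ng * nu < 2**62:
        key = (g_codes * nb + b_codes) * nu + u_codes
        key.sort(kind="quicksort")
        distinct = key[np.r_[True, key[1:] != key[:-1]]] if len(key) else key
        pairs = distinct // nu
        mat = np.bincount(pairs, minlength=ng * nb).reshape(ng, nb)
        frame = pd.DataFrame(mat, index=pd.Index(g_names), columns=pd.Index(b_names))
        observed_g = mat.sum(axis=1) > 0
        observed_b = mat.sum(axis=0) > 0
        if not observed_g.all() or not observed_b.all():
            frame = frame.loc[observed_g, observed_b]
    else:
        triples = pd.DataFrame(
            {"barcode": barcode[keep], "umi": umi[keep], "gene": gene[keep]}
        ).drop_duplicates()
        frame = (
            triples.groupby(["gene", "barcode"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
    return frame.sort_index(axis=0).sort_index(axis=1)


def barcode_rank(data: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Barcodes ordered by descending read count, with cumulative fractions.

    Accepts per-barcode read totals (a Series) or a tagged-read / molecule
    table (rows are counted per barcode; an ``n_reads`` column, if present,
    is summed).  Ties are broken lexicographically by barcode.  This is the
    substrate of the knee plot used for cell-number selection.
    """
    if isinstance(data, pd.DataFrame):
        if "n_reads" in data.columns:
            totals = data.groupby("barcode", observed=True)["n_reads"].sum()
        else:
            totals = data.groupby("barcode", observed=True).size()
        totals = totals[totals > 0]
    else:
        totals = data
    if totals is None or len(totals) == 0:
        raise ValueError("barcode_rank requires at least one barcode")
    if (totals < 0).any():
        raise ValueError("read totals must be non-negative")
    table = totals.rename("read_count").rename_axis("barcode").reset_index()
    table["barcode"] = table["barcode"].astype(str)
    table = table.sort_values("barcode", kind="stable")
    table = table.sort_values("read_count", ascending=False, kind="stable")
    table = table.reset_index(drop=True)
    total = table["read_count"].sum()
    if total == 0:
        raise ValueError("all read totals are zero")
    table["cumulative_fraction"] = table["read_count"].cumsum() / total
    table.index = pd.RangeIndex(1, len(table) + 1, name="rank")
    return table


def barcode_base_composition(
    barcodes: Sequence[str] | pd.DataFrame,
    weights: Sequence[float] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Positional base frequencies of cell barcodes, and the last-base T excess.

    Returns a 12 x 4 frequency matrix (positions 1-12 by A/C/G/T, each row
    summing to 1) and the T-excess score: the T frequency at position 12
    minus the mean T frequency over positions 1-11.  A positive excess is
    the signature of bead-synthesis errors that leave a templated T as the
    last barcode base.  Frequencies are per unique barcode by default;
    pass ``weights`` (e.g. read counts) to weight beads by coverage.
    """
    if isinstance(barcodes, pd.DataFrame):
        barcodes = barcodes["barcode"]
    barcodes = pd.Index(barcodes).astype(str)
    if len(barcodes) == 0:
        raise ValueError("at least one barcode is required")
    if not (barcodes.str.len() == BARCODE_LENGTH).all():
        raise ValueError(f"barcodes must be {BARCODE_LENGTH}-mers")
    chars = barcodes.to_numpy().astype(f"U{BARCODE_LENGTH}")
    mat = chars.view("U1").reshape(len(chars), BARCODE_LENGTH)
    if weights is None:
        w = np.ones(len(chars))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(chars),):
            raise ValueError("weights must match the number of barcodes")
    freq = np.empty((BARCODE_LENGTH, 4))
    for j, base in enumerate("ACGT"):
        freq[:, j] = ((mat == base) * w[:, None]).sum(axis=0) / w.sum()
    table = pd.DataFrame(
        freq, index=pd.RangeIndex(1, BARCODE_LENGTH + 1, name="position"),
        columns=list("ACGT"),
    )
    t_excess = float(table.loc[BARCODE_LENGTH, "T"] - table.loc[: BARCODE_LENGTH - 1, "T"].mean())
    return table, t_excess
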