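"""Readers and writers for the toolkit's plain-text interchange formats.

Two DGE dialects are supported:

* dense TSV — header row of cell barcodes with a leading ``GENE`` column of
  gene identifiers (the DigitalExpression convention); the canonical
  interchange format.
* sparse triplet — a Matrix Market coordinate file ``matrix.mtx`` plus
  ``genes.tsv`` and ``barcodes.tsv`` list files, for matrices too large to
  store densely.

Both round-trip losslessly.  Tagged reads, gene annotations, simulation
truth tables and simulation parameters are TSV/JSON sidecars.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from pandas.errors import ParserError

from .dge import DgeMatrix, GeneAnnotation

__all__ = [
    "read_dge",
    "write_dge",
    "read_dge_dense",
    "write_dge_dense",
    "read_dge_mtx",
    "write_dge_mtx",
    "read_tagged_reads",
    "write_tagged_reads",
    "read_annotation",
    "write_annotation",
    "write_truth",
    "read_truth",
    "write_read1_fastq",
]

DENSE_HEADER = "GENE"


def write_dge_dense(dge: DgeMatrix, path: str | os.PathLike) -> None:
    frame = dge.counts.copy()
    frame.index.name = DENSE_HEADER
    frame.to_csv(path, sep="\t")


def read_dge_dense(path: str | os.PathLike) -> DgeMatrix:
    try:
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype_backend="numpy_nullable")
    except ParserError as exc:
        raise ValueError(f"malformed dense DGE file {path}: {exc}") from exc
    if frame.index.name != DENSE_HEADER:
        raise ValueError(
            f"dense DGE file {path} must start with a {DENSE_HEADER!r} column, "
            f"got {frame.index.name!r}"
        )
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        line = int(np.nonzero(frame.index == dup)[0][1]) + 2  # +1 header, +1 one-based
        raise ValueError(f"duplicate gene {dup!r} in {path} at line {line}")
    if frame.isna().any().any():
        row = int(np.nonzero(frame.isna().any(axis=1).to_numpy())[0][0])
        raise ValueError(f"missing value in {path} at line {row + 2}")
    try:
        values = frame.to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
    if not np.array_equal(values, np.round(values)) or (values < 0).any():
        bad = np.nonzero(((values != np.round(values)) | (values < 0)).any(axis=1))[0][0]
        raise ValueError(
            f"non-integer or negative count in {path} at line {int(bad) + 2}"
        )
    return DgeMatrix(frame.astype(np.int64))


def write_dge_mtx(dge: DgeMatrix, directory: str | os.PathLike) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(dge.counts.to_numpy())
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse, field="integer")
    dge.gene_ids.to_series().to_csv(directory / "genes.tsv", sep="\t", index=False, header=False)
    dge.cell_barcodes.to_series().to_csv(
        directory / "barcodes.tsv", sep="\t", index=False, header=False
    )


def read_dge_mtx(directory: str | os.PathLike) -> DgeMatrix:
    directory = Path(directory)
    matrix = scipy.io.mmread(str(directory / "matrix.mtx"))
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    dense = np.asarray(scipy.sparse.coo_matrix(matrix).todense())
    if dense.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match {len(genes)} genes x "
            f"{len(barcodes)} barcodes in {directory}"
        )
    return DgeMatrix(pd.DataFrame(dense, index=genes, columns=barcodes))


def write_dge(dge: DgeMatrix, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write a DGE matrix: ``tsv`` (dense) or ``mtx`` (sparse triplet directory)."""
    if format == "tsv":
        write_dge_dense(dge, path)
    elif format == "mtx":
        write_dge_mtx(dge, path)
    else:
        raise ValueError(f"unknown DGE format {format!r} (expected 'tsv' or 'mtx')")


def read_dge(path: str | os.PathLike, format: str | None = None) -> DgeMatrix:
    if format is None:
        format = "mtx" if Path(path).is_dir() else "tsv"
    if format == "tsv":
        return read_dge_dense(path)
    if format == "mtx":
        return read_dge_mtx(path)
    raise ValueError(f"unknown DGE format {format!r} (expected 'tsv' or 'mtx')")


def write_tagged_reads(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    """Tagged-read TSV: one row per read, columns barcode, umi, gene.

    The gene field is empty for reads not assigned to a gene.
    """
    out = reads.loc[:, ["barcode", "umi", "gene"]].copy()
    out.to_csv(path, sep="\t", index=False)


def read_tagged_reads(path: str | os.PathLike) -> pd.DataFrame:
    reads = pd.read_csv(
        path, sep="\t", dtype={"barcode": str, "umi": str, "gene": str},
        keep_default_na=False,
    )
    missing = [c for c in ("barcode", "umi", "gene") if c not in reads.columns]
    if missing:
        raise ValueError(f"tagged-read file {path} is missing columns: {missing}")
    reads.loc[reads["gene"] == "", "gene"] = pd.NA
    return reads


def write_read1_fastq(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    """Emit read 1 as FASTQ: the 20-mer barcode+UMI, gene label in the header comment."""
    with open(path, "w") as handle:
        for i, row in enumerate(reads.itertuples(index=False)):
            gene = "" if pd.isna(row.gene) else str(row.gene)
            seq = f"{row.barcode}{row.umi}"
            handle.write(f"@read{i} gene={gene}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_annotation(annotation: GeneAnnotation, path: str | os.PathLike) -> None:
    annotation.table.to_csv(path, sep="\t")


def read_annotation(path: str | os.PathLike) -> GeneAnnotation:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return GeneAnnotation(table)


def write_truth(truth, path: str | os.PathLike) -> None:
    """Truth table TSV; simulation parameters go in a JSON sidecar ``<path>.params.json``."""
    truth.barcodes.to_csv(path, sep="\t", index=False)
    Path(f"{path}.params.json").write_text(truth.params.to_json())


def read_truth(path: str | os.PathLike):
    from .simulate import SimParams, SimTruth

    barcodes = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    params = SimParams.from_json(Path(f"{path}.params.json").read_text())
    return SimTruth(barcodes, params)
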