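"""Droplet-run simulator with ground truth.

Emulates the read structure of a Drop-seq style experiment: a minority of
beads capture one (occasionally two) cells, while the vast majority of beads
are exposed only to ambient RNA and accumulate a handful of reads.  Each
captured mRNA molecule carries a 12 bp cell barcode and an 8 bp UMI and is
amplified into one or more duplicate reads.  A configurable fraction of
barcodes suffers a bead-synthesis defect that overwrites the last barcode
base with T, mimicking the T-bias observed on real beads.

The simulator returns both the tagged-read stream and a per-barcode ground
truth ledger (:class:`SimTruth`), so that cell selection, doublet estimation
and QC statistics can be validated against known answers.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dge import GeneAnnotation

__all__ = [
    "SimParams",
    "SimTruth",
    "gene_table",
    "simulate_annotation",
    "simulate_expression_profiles",
    "simulate_molecules",
    "simulate_run",
    "make_barnyard",
    "read_totals",
]

BARCODE_LENGTH = 12
UMI_LENGTH = 8
_UMI_SPACE = 4**UMI_LENGTH
_BARCODE_SPACE = 4**BARCODE_LENGTH
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of a simulated droplet run.

    Defaults describe a two-species (human/mouse) cell-line mixture at desk
    scale: ~150 cells against ~3000 ambient-only beads (>95 % of beads see
    only ambient RNA), a median library of ~5000 UMIs per cell, four reads
    per molecule, and a 10 % co-encapsulation (doublet) rate.
    """

    n_cells: int = 150
    species_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"human": 0.5, "mouse": 0.5}
    )
    n_genes_per_species: int = 2000
    expression_profile_dispersion: float = 1.5
    library_size_log_mean: float = math.log(5000.0)
    library_size_log_sd: float = 0.4
    doublet_rate: float = 0.10
    n_ambient_barcodes: int = 3000
    ambient_reads_mean: float = 100.0
    reads_per_umi_mean: float = 4.0
    mito_gene_fraction: float = 0.01
    mito_expression_fraction: float = 0.10
    last_base_t_error_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_ambient_barcodes < 0:
            raise ValueError("n_cells and n_ambient_barcodes must be >= 0")
        if self.n_genes_per_species <= 0:
            raise ValueError("n_genes_per_species must be positive")
        if not np.isfinite(self.expression_profile_dispersion):
            raise ValueError("expression_profile_dispersion must be finite")
        if self.expression_profile_dispersion < 0:
            raise ValueError("expression_profile_dispersion must be >= 0")
        if self.reads_per_umi_mean < 1:
            raise ValueError("reads_per_umi_mean must be >= 1")
        if self.ambient_reads_mean < 0:
            raise ValueError("ambient_reads_mean must be >= 0")
        for name in (
            "doublet_rate",
            "mito_gene_fraction",
            "mito_expression_fraction",
            "last_base_t_error_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        props = dict(self.species_proportions)
        if not props:
            raise ValueError("at least one species is required")
        if any(p < 0 for p in props.values()):
            raise ValueError("species proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-6:
            raise ValueError("species_proportions must sum to 1")

    @property
    def species(self) -> list[str]:
        return list(self.species_proportions)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["species_proportions"] = dict(self.species_proportions)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimParams":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth ledger of a simulated run.

    ``barcodes`` holds one row per emitted barcode with columns
    ``barcode`` (the observed 12-mer, after any last-base corruption),
    ``origin`` (``singlet`` / ``doublet`` / ``ambient_only``),
    ``species_1`` / ``species_2`` (labels of the contained cell(s); NA for
    ambient-only beads, ``species_2`` only set for doublets),
    ``total_umis`` (distinct molecules attributed to the barcode, ambient
    molecules included so that totals tie out against the read stream),
    ``mito_umis`` and ``last_base_corrupted``.
    """

    barcodes: pd.DataFrame
    params: SimParams

    def __post_init__(self) -> None:
        if self.barcodes["barcode"].duplicated().any():
            raise ValueError("truth barcodes must be unique")

    @property
    def cell_barcodes(self) -> pd.Index:
        mask = self.barcodes["origin"] != "ambient_only"
        return pd.Index(self.barcodes.loc[mask, "barcode"])


def _rngs(params: SimParams) -> dict[str, np.random.Generator]:
    # One sub-stream per component: adding ambient barcodes, changing the
    # duplication rate etc. never perturbs the cell draws.
    names = ("profiles", "annotation", "cells", "ambient", "umi", "duplication", "barcodes")
    children = np.random.SeedSequence(params.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def encode_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Decode integer codes in [0, 4**k) into k-mer strings over ACGT."""
    codes = np.ascontiguousarray(codes, dtype=np.uint64)
    shifts = (2 * np.arange(k - 1, -1, -1)).astype(np.uint64)
    digits = (codes[:, None] >> shifts) & np.uint64(3)
    return _BASE_BYTES[digits.astype(np.intp)].view(f"S{k}").ravel().astype(str)


def _draw_distinct_codes(
    rng: np.random.Generator, group_ids: np.ndarray, space: int
) -> np.ndarray:
    """Draw one code per element, uniform on [0, space), distinct within groups."""
    n = len(group_ids)
    codes = rng.integers(0, space, size=n, dtype=np.int64)
    key = group_ids.astype(np.int64) * space + codes
    for _ in range(200):
        dup = pd.Index(key).duplicated(keep="first")
        if not dup.any():
            return codes
        codes[dup] = rng.integers(0, space, size=int(dup.sum()), dtype=np.int64)
        key[dup] = group_ids[dup].astype(np.int64) * space + codes[dup]
    raise RuntimeError("could not resolve code collisions; group larger than code space?")


def gene_table(params: SimParams) -> pd.DataFrame:
    """Deterministic gene universe: per species, mito genes first then the rest.

    Gene identifiers carry the species label as a prefix (combined-reference
    convention), with mitochondrial genes named ``<species>_MT...``.
    """
    rows = []
    for sp in params.species:
        n = params.n_genes_per_species
        n_mito = int(round(params.mito_gene_fraction * n))
        for j in range(n_mito):
            rows.append((f"{sp}_MT{j:03d}", sp, True))
        for j in range(n - n_mito):
            rows.append((f"{sp}_G{j:05d}", sp, False))
    return pd.DataFrame(rows, columns=["gene_id", "species", "is_mito"])


def simulate_annotation(params: SimParams) -> GeneAnnotation:
    """Gene annotation for the simulated universe.

    Mean isoform lengths are drawn log-normally around ~1.5 kb, the typical
    scale of mammalian mRNAs.
    """
    rng = _rngs(params)["annotation"]
    genes = gene_table(params)
    lengths = rng.lognormal(math.log(1500.0), 0.5, size=len(genes))
    table = genes.assign(mean_isoform_length=np.round(lengths, 1)).set_index("gene_id")
    return GeneAnnotation(table)


def simulate_expression_profiles(params: SimParams) -> dict[str, pd.Series]:
    """Per-species gene-mean vectors, each normalized to sum to one.

    Per-gene means are log-normal with the configured dispersion; the
    mitochondrial gene block is rescaled so it jointly carries an expected
    fraction ``mito_expression_fraction`` of a cell's molecules.  With
    dispersion 0 every gene within a block gets equal mass.
    """
    rng = _rngs(params)["profiles"]
    genes = gene_table(params)
    sigma = params.expression_profile_dispersion
    profiles: dict[str, pd.Series] = {}
    for sp in params.species:
        sub = genes[genes["species"] == sp]
        if sigma == 0:
            w = np.ones(len(sub))
        else:
            w = rng.lognormal(0.0, sigma, size=len(sub))
        mito = sub["is_mito"].to_numpy()
        mef = params.mito_expression_fraction
        if mito.any() and (~mito).any():
            w[mito] *= mef / w[mito].sum()
            w[~mito] *= (1.0 - mef) / w[~mito].sum()
        else:
            w /= w.sum()
        profiles[sp] = pd.Series(w, index=pd.Index(sub["gene_id"], name="gene_id"))
    return profiles


def _corrupt_barcodes(
    rng: np.random.Generator, n: int, error_prob: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n unique barcode codes and apply the last-base-to-T defect.

    The defect is a bead-synthesis error, so all reads of a bead share it;
    post-corruption collisions at 12-mer scale are regenerated so observed
    barcodes stay unique and molecule counts are conserved.
    """
    codes = _draw_distinct_codes(rng, np.zeros(n, dtype=np.int64), _BARCODE_SPACE)
    corrupted = rng.random(n) < error_prob
    final = np.where(corrupted, codes | 3, codes)  # base 12 occupies the low 2 bits; T == 3
    for _ in range(200):
        dup = pd.Index(final).duplicated(keep="first")
        if not dup.any():
            return final, corrupted
        redraw = rng.integers(0, _BARCODE_SPACE, size=int(dup.sum()), dtype=np.int64)
        codes[dup] = redraw
        final = np.where(corrupted, codes | 3, codes)
    raise RuntimeError("could not resolve barcode collisions")


def simulate_molecules(params: SimParams) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a run at molecule resolution.

    Returns a molecule table with one row per distinct (barcode, UMI, gene)
    triple and an ``n_reads`` column (>= 1, shifted-Poisson duplication),
    plus the ground-truth ledger.  :func:`simulate_run` expands this table
    into the duplicate-read stream.
    """
    rngs = _rngs(params)
    genes = gene_table(params)
    gene_ids = genes["gene_id"].to_numpy()
    is_mito = genes["is_mito"].to_numpy()
    n_genes_total = len(genes)
    species = params.species
    props = np.array([params.species_proportions[s] for s in species], dtype=float)

    profiles = simulate_expression_profiles(params)
    # Global per-species probability vectors aligned to the gene universe.
    offsets = {}
    global_profiles = {}
    start = 0
    for sp in species:
        offsets[sp] = start
        vec = np.zeros(n_genes_total)
        vec[start : start + params.n_genes_per_species] = profiles[sp].to_numpy()
        global_profiles[sp] = vec
        start += params.n_genes_per_species

    # --- cell-containing barcodes -------------------------------------
    n_cells = params.n_cells
    rng_c = rngs["cells"]
    primary = rng_c.choice(len(species), size=n_cells, p=props) if n_cells else np.empty(0, int)
    is_doublet = rng_c.random(n_cells) < params.doublet_rate
    secondary = rng_c.choice(len(species), size=n_cells, p=props) if n_cells else np.empty(0, int)

    comp_barcode = np.concatenate([np.arange(n_cells), np.nonzero(is_doublet)[0]])
    comp_species = np.concatenate([primary, secondary[is_doublet]]).astype(int)
    n_comp = len(comp_barcode)
    lib = np.maximum(
        1,
        np.rint(
            rng_c.lognormal(params.library_size_log_mean, params.library_size_log_sd, size=n_comp)
        ),
    ).astype(np.int64)

    mol_barcode = np.repeat(comp_barcode, lib)
    mol_gene = np.empty(int(lib.sum()), dtype=np.int64)
    for s_idx, sp in enumerate(species):
        comp_mask = comp_species == s_idx
        mol_mask = np.repeat(comp_mask, lib)
        k = int(mol_mask.sum())
        if k:
            local = rng_c.choice(
                params.n_genes_per_species, size=k, p=profiles[sp].to_numpy()
            )
            mol_gene[mol_mask] = local + offsets[sp]

    # --- ambient-only barcodes ----------------------------------------
    rng_a = rngs["ambient"]
    n_amb = params.n_ambient_barcodes
    amb_mol_rate = params.ambient_reads_mean / params.reads_per_umi_mean
    amb_counts = rng_a.poisson(amb_mol_rate, size=n_amb) if n_amb else np.empty(0, int)
    pooled = sum(p * global_profiles[sp] for p, sp in zip(props, species))
    pooled = np.asarray(pooled, dtype=float)
    pooled /= pooled.sum()
    amb_total = int(amb_counts.sum())
    amb_gene = rng_a.choice(n_genes_total, size=amb_total, p=pooled) if amb_total else np.empty(0, int)
    amb_barcode = n_cells + np.repeat(np.arange(n_amb), amb_counts)

    mol_barcode = np.concatenate([mol_barcode, amb_barcode])
    mol_gene = np.concatenate([mol_gene, amb_gene])

    # --- UMIs: distinct within (barcode, gene) ------------------------
    group = mol_barcode * n_genes_total + mol_gene
    umi_codes = _draw_distinct_codes(rngs["umi"], group, _UMI_SPACE)

    # --- PCR duplication ----------------------------------------------
    n_reads = 1 + rngs["duplication"].poisson(
        params.reads_per_umi_mean - 1.0, size=len(mol_barcode)
    )

    # --- barcodes and the last-base defect ----------------------------
    n_bar = n_cells + n_amb
    final_codes, corrupted = _corrupt_barcodes(
        rngs["barcodes"], n_bar, params.last_base_t_error_prob
    )
    barcode_str = encode_kmers(final_codes, BARCODE_LENGTH)

    molecules = pd.DataFrame(
        {
            "barcode": pd.Categorical.from_codes(mol_barcode, categories=barcode_str),
            "umi": encode_kmers(umi_codes, UMI_LENGTH),
            "gene": pd.Categorical.from_codes(mol_gene, categories=gene_ids),
            "n_reads": n_reads.astype(np.int64),
        }
    )

    total_umis = np.bincount(mol_barcode, minlength=n_bar).astype(np.int64)
    mito_umis = np.bincount(
        mol_barcode, weights=is_mito[mol_gene].astype(float), minlength=n_bar
    ).astype(np.int64)
    origin = np.full(n_bar, "ambient_only", dtype=object)
    if n_cells:
        origin[:n_cells] = np.where(is_doublet, "doublet", "singlet")
    species_arr = np.array(species, dtype=object)
    species_1 = np.full(n_bar, pd.NA, dtype=object)
    species_2 = np.full(n_bar, pd.NA, dtype=object)
    if n_cells:
        species_1[:n_cells] = species_arr[primary]
        species_2[:n_cells][is_doublet] = species_arr[secondary[is_doublet]]
    truth_df = pd.DataFrame(
        {
            "barcode": barcode_str,
            "origin": origin,
            "species_1": species_1,
            "species_2": species_2,
            "total_umis": total_umis,
            "mito_umis": mito_umis,
            "last_base_corrupted": corrupted,
        }
    )
    return molecules, SimTruth(truth_df, params)


def simulate_run(params: SimParams) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a run and return the tagged-read stream and ground truth.

    The stream has one row per read with columns ``barcode``, ``umi``,
    ``gene``; every molecule appears at least once and PCR duplicates are
    exact copies of the molecule's row.
    """
    molecules, truth = simulate_molecules(params)
    reads = molecules.loc[
        molecules.index.repeat(molecules["n_reads"]), ["barcode", "umi", "gene"]
    ].reset_index(drop=True)
    return reads, truth


def make_barnyard(params: SimParams) -> tuple[pd.DataFrame, SimTruth]:
    """Two-species mixing run (barnyard design) with disjoint gene namespaces."""
    if len(params.species) != 2:
        raise ValueError(
            f"a barnyard run requires exactly two species, got {len(params.species)}"
        )
    return simulate_run(params)


def read_totals(reads: pd.DataFrame) -> pd.Series:
    """Per-barcode read totals from a tagged-read or molecule table."""
    if "n_reads" in reads.columns:
        totals = reads.groupby("barcode", observed=True)["n_reads"].sum()
    else:
        totals = reads.groupby("barcode", observed=True).size()
    totals.name = "read_count"
    totals.index.name = "barcode"
    return totals[totals > 0].astype(np.int64)
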