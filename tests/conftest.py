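import numpy as np
import pandas as pd
import pytest

from dropkit import DgeMatrix, GeneAnnotation


@pytest.fixture
def annotation() -> GeneAnnotation:
    table = pd.DataFrame(
        {
            "gene_id": ["hg_A", "hg_B", "hg_MT1", "mm_A", "mm_B", "mm_MT1"],
            "species": ["human"] * 3 + ["mouse"] * 3,
            "is_mito": [False, False, True, False, False, True],
            "mean_isoform_length": [1000.0, 500.0, 800.0, 1500.0, 2000.0, 700.0],
        }
    )
    return GeneAnnotation(table)


@pytest.fixture
def small_dge() -> DgeMatrix:
    counts = pd.DataFrame(
        {
            "AAAAAAAAAAAA": [50, 30, 10, 0, 0, 0],
            "CCCCCCCCCCCC": [0, 0, 0, 40, 50, 5],
            "GGGGGGGGGGGG": [20, 20, 5, 30, 20, 5],
        },
        index=["hg_A", "hg_B", "hg_MT1", "mm_A", "mm_B", "mm_MT1"],
    )
    return DgeMatrix(counts)


def random_dge(rng: np.random.Generator, n_genes: int, n_cells: int,
               max_count: int = 20, density: float = 0.5) -> DgeMatrix:
    counts = rng.integers(0, max_count + 1, size=(n_genes, n_cells))
    counts = np.where(rng.random((n_genes, n_cells)) < density, counts, 0)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    barcodes = [_int_to_barcode(i) for i in range(n_cells)]
    return DgeMatrix(pd.DataFrame(counts, index=genes, columns=barcodes))


def _int_to_barcode(i: int) -> str:
    bases = "ACGT"
    return "".join(bases[(i >> (2 * k)) & 3] for k in range(12))
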