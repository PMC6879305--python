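import numpy as np
import pytest

from tigs.io_formats import ExpressionMatrix, GeneSet, MutationRecord, MutationTable


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    """4 genes x 3 samples, fixed values."""
    values = np.array(
        [
            [1.0, 2.0, 3.0],
            [5.0, 5.0, 5.0],
            [2.5, 0.5, 9.0],
            [7.0, 1.0, 4.0],
        ]
    )
    return ExpressionMatrix(["G1", "G2", "G3", "G4"], ["S1", "S2", "S3"], values)


@pytest.fixture
def random_expr():
    """Factory for seeded random expression matrices."""

    def make(n_genes=20, n_samples=6, seed=0):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            [f"G{i}" for i in range(n_genes)],
            [f"S{j}" for j in range(n_samples)],
            rng.normal(5, 2, size=(n_genes, n_samples)),
        )

    return make


@pytest.fixture
def toy_maf() -> MutationTable:
    rows = [
        ("P1", "TP53", "Missense_Mutation"),
        ("P1", "KRAS", "Missense_Mutation"),
        ("P1", "EGFR", "Silent"),
        ("P2", "B2M", "Nonsense_Mutation"),
        ("P2", "BRAF", "Intron"),
        ("P3", "B2M", "Missense_Mutation"),
        ("P3", "TP53", "Frame_Shift_Del"),
    ]
    return MutationTable([MutationRecord(*r) for r in rows])


@pytest.fixture
def five_gene_set() -> GeneSet:
    return GeneSet("five", ["G1", "G3", "G5", "G7", "G11"])
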