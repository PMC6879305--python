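"""Built-in gene lists for the scoring pipeline.

``APM_GENES`` is the 18-gene MHC class I antigen processing and
presenting machinery list (proteasome subunits, TAP transporters, ER
chaperones, B2M, classical HLA class I).  ``IFNG_GENES``, ``CD8_GENES``
and ``PDL1_GENES`` are the published mean-expression response
signatures.

The immune cell-type collection used for the immune infiltration score
and the interferon signatures IFNG.GS / ISG.RS are distributed as
supplementary material by their original publications; this package
ships SYNTHETIC placeholder gene lists under the same set names so that
the full pipeline is runnable and testable without those files.  Real
collections can be supplied as GMT files wherever a signature collection
is accepted.
"""

from __future__ import annotations

from .io_formats import GeneSet

#: MHC class I antigen processing and presenting machinery (18 genes).
APM_GENES: list[str] = [
    "PSMB5",
    "PSMB6",
    "PSMB7",
    "PSMB8",
    "PSMB9",
    "PSMB10",
    "TAP1",
    "TAP2",
    "ERAP1",
    "ERAP2",
    "CANX",
    "CALR",
    "PDIA3",
    "TAPBP",
    "B2M",
    "HLA-A",
    "HLA-B",
    "HLA-C",
]

#: Interferon-gamma response signature (mean expression).
IFNG_GENES: list[str] = ["IFNG", "STAT1", "IDO1", "CXCL10", "CXCL9", "HLA-DRA"]

#: Cytotoxic T-cell signature (mean expression).
CD8_GENES: list[str] = ["CD8A", "CD8B"]

#: PD-L1 expression biomarker (single gene).
PDL1_GENES: list[str] = ["CD274"]

#: Immune cell types entering the immune infiltration score.
IMMUNE_CELL_TYPES: list[str] = [
    "Macrophages",
    "DC",
    "aDC",
    "iDC",
    "pDC",
    "B cells",
    "Cytotoxic cells",
    "Eosinophils",
    "Mast cells",
    "Neutrophils",
    "NK cells",
    "NK CD56bright cells",
    "NK CD56dim cells",
    "CD8 T cells",
    "T helper cells",
    "Tcm",
    "Tem",
    "Th1 cells",
    "Th2 cells",
    "Th17 cells",
    "Treg",
]

_GENES_PER_CELL_TYPE = 5


def apm_gene_set() -> GeneSet:
    return GeneSet("APM", list(APM_GENES))


def expression_signature_sets() -> dict[str, GeneSet]:
    """The mean-expression signature panel keyed by biomarker name.

    IFNG, CD8 and PDL1 carry their published member genes; ifng_gs and
    isg_rs are synthetic placeholders (see module docstring).
    """
    return {
        "ifng": GeneSet("IFNG", list(IFNG_GENES)),
        "cd8": GeneSet("CD8", list(CD8_GENES)),
        "pdl1": GeneSet("PDL1", list(PDL1_GENES)),
        "ifng_gs": GeneSet("IFNG.GS", synthetic_signature_genes("IFNG.GS", 20)),
        "isg_rs": GeneSet("ISG.RS", synthetic_signature_genes("ISG.RS", 20)),
    }


def synthetic_signature_genes(name: str, n: int) -> list[str]:
    """Deterministic synthetic gene symbols standing in for a signature
    whose real member list is not bundled."""
    slug = name.replace(".", "_").replace(" ", "_").upper()
    return [f"SYN_{slug}_{i:02d}" for i in range(1, n + 1)]


def synthetic_immune_cell_sets() -> list[GeneSet]:
    """Synthetic placeholder marker lists, one per immune cell type."""
    return [
        GeneSet(ct, synthetic_signature_genes(ct, _GENES_PER_CELL_TYPE))
        for ct in IMMUNE_CELL_TYPES
    ]
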