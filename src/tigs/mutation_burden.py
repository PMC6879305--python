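"""Tumor mutational burden from MAF mutation tables.

TMB is the number of non-synonymous somatic alterations per megabase of
exome examined; 38 Mb is the standard whole-exome estimate.  The module
also flags beta-2-microglobulin (B2M) loss-of-function events, which
abolish MHC class I surface presentation and zero out the normalized
antigen-presentation score downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MutationTable

logger = logging.getLogger(__name__)

#: MAF classes counted as non-synonymous (protein-altering).  Standard
#: MAF convention; configurable via the ``classes`` arguments below.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: Truncating / translation-aborting classes treated as loss of function.
LOF_CLASSES = frozenset(
    {
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
    }
)

#: Whole-exome size estimate in megabases.
DEFAULT_EXOME_SIZE_MB = 38.0


@dataclass
class TmbResult:
    """Per-sample non-synonymous counts and mutations/Mb."""

    sample_ids: list[str]
    n_nonsynonymous: np.ndarray
    tmb: np.ndarray
    exome_size_mb: float
    no_variants_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.n_nonsynonymous = np.asarray(self.n_nonsynonymous, dtype=int)
        self.tmb = np.asarray(self.tmb, dtype=float)
        if self.no_variants_flag is None:
            self.no_variants_flag = self.n_nonsynonymous == 0
        if np.any(self.tmb < 0) or self.exome_size_mb <= 0:
            raise ValueError("tmb must be >= 0 and exome_size_mb > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_nonsynonymous": self.n_nonsynonymous,
                "tmb": self.tmb,
                "no_variants": self.no_variants_flag,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )

    def tmb_series(self) -> pd.Series:
        return pd.Series(self.tmb, index=self.sample_ids, name="tmb")


def filter_nonsynonymous(
    muts: MutationTable, classes: frozenset[str] | set[str] = NONSYNONYMOUS_CLASSES
) -> MutationTable:
    """Keep only records whose Variant_Classification is non-synonymous.

    Counts of every dropped class (including unknown strings, which are
    dropped and flagged) are logged; an empty result is legal.
    """
    kept = [r for r in muts.records if r.variant_classification in classes]
    dropped = [r for r in muts.records if r.variant_classification not in classes]
    if dropped:
        counts: dict[str, int] = {}
        for r in dropped:
            counts[r.variant_classification] = counts.get(r.variant_classification, 0) + 1
        logger.info("filter_nonsynonymous dropped %d records: %s", len(dropped), counts)
    return MutationTable(kept)


def compute_tmb(
    muts: MutationTable,
    samples: Sequence[str],
    exome_size_mb: float = DEFAULT_EXOME_SIZE_MB,
) -> TmbResult:
    """TMB = non-synonymous count / exome megabases, per sample.

    ``muts`` must already be non-synonymous-filtered.  ``samples``
    enumerates the cohort so that samples with no observed variants get a
    count of 0 (and a flag) rather than disappearing.
    """
    if exome_size_mb <= 0:
        raise ValueError(f"exome_size_mb must be > 0, got {exome_size_mb}")
    counts = {s: 0 for s in samples}
    for r in muts.records:
        if r.sample_id in counts:
            counts[r.sample_id] += 1
    n = np.array([counts[s] for s in samples], dtype=int)
    return TmbResult(list(samples), n, n / exome_size_mb, exome_size_mb)


def detect_b2m_lof(
    muts: MutationTable,
    samples: Sequence[str] | None = None,
    lof_classes: frozenset[str] | set[str] = LOF_CLASSES,
) -> pd.Series:
    """Flag samples carrying >= 1 B2M record in a loss-of-function class.

    When ``samples`` is given the result covers exactly that cohort
    (absent samples are False); otherwise it covers the samples seen in
    ``muts``.
    """
    hit = {
        r.sample_id
        for r in muts.records
        if r.gene_symbol == "B2M" and r.variant_classification in lof_classes
    }
    index = list(samples) if samples is not None else muts.sample_ids
    return pd.Series([s in hit for s in index], index=index, name="b2m_lof")
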