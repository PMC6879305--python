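"""Assembly of the tumor immunogenicity score and its comparator panel.

The tumor immunogenicity score combines the two determinants of whether
a tumor can be recognized by T cells:

* antigen processing and presentation efficiency, measured as a
  single-sample enrichment score (APS) of the 18-gene antigen
  presentation machinery list, rescaled to [0, 1] by a pan-cancer (or
  cohort) min/max reference and forced to 0 for tumors carrying a B2M
  loss-of-function mutation; and
* tumor antigenicity, measured as log tumor mutational burden.

    TIGS = APS_normalized x ln(TMB + 1)

The pseudo-count keeps the score defined (and non-negative) for tumors
below one mutation/Mb.  The module also computes the immune infiltration
score (mean of across-sample-standardized cell-type enrichment scores)
and the mean-expression comparator signatures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import (
    GsvaParams,
    gsva_scores,
    kernel_cdf_transform,
    mean_signature_score,
    random_control_scores,
    rank_walk_scores,
)
from .io_formats import ExpressionMatrix, GeneSet, MutationTable
from .mutation_burden import (
    DEFAULT_EXOME_SIZE_MB,
    compute_tmb,
    detect_b2m_lof,
    filter_nonsynonymous,
)
from .signatures import apm_gene_set, expression_signature_sets, synthetic_immune_cell_sets

logger = logging.getLogger(__name__)


@dataclass
class NormalizationReference:
    """Min/max APS used to rescale raw enrichment scores to [0, 1].

    ``cohort_derived`` references come from the scored cohort itself;
    ``user_supplied`` ones (e.g. a pan-cancer min/max) allow cross-cohort
    comparability, with out-of-range cohort values clipped.
    """

    aps_min: float
    aps_max: float
    source: str = "user_supplied"

    def __post_init__(self) -> None:
        if not (self.aps_min < self.aps_max):
            raise ValueError(
                f"degenerate normalization reference: min {self.aps_min} must be "
                f"< max {self.aps_max}"
            )
        if not (-1 <= self.aps_min <= 1 and -1 <= self.aps_max <= 1):
            raise ValueError("reference bounds must lie in [-1, 1]")

    @classmethod
    def from_cohort(cls, aps: pd.Series | np.ndarray) -> "NormalizationReference":
        a = np.asarray(aps, dtype=float)
        return cls(float(a.min()), float(a.max()), source="cohort_derived")


def compute_aps(
    expr: ExpressionMatrix,
    apm_set: GeneSet | None = None,
    params: GsvaParams | None = None,
) -> pd.Series:
    """Per-sample antigen presentation score: the rank-walk enrichment of
    the antigen presentation machinery gene list (raw, in [-1, 1])."""
    apm_set = apm_set or apm_gene_set()
    sm = gsva_scores(expr, [apm_set], params)
    if not sm.set_names:
        raise ValueError(
            f"APM set {apm_set.name!r} could not be scored (too few genes present)"
        )
    return sm.to_frame().iloc[0].rename("aps")


def normalize_aps(
    aps: pd.Series,
    ref: NormalizationReference | None = None,
    b2m_flags: pd.Series | None = None,
) -> pd.Series:
    """Rescale raw APS to [0, 1]: (APS - min) / (max - min).

    With no ``ref`` the cohort's own min/max is used, derived over
    B2M-wild-type samples (flagged samples are overridden to 0 anyway,
    so letting them set the extremes would shrink everyone else's
    range).  A user-supplied reference that does not bracket the cohort
    leads to clipping (logged).  Samples flagged for B2M loss of
    function are set to 0 after scaling.
    """
    if ref is None:
        basis = aps
        if b2m_flags is not None:
            wt = ~b2m_flags.reindex(aps.index).fillna(False).astype(bool)
            if wt.any():
                basis = aps[wt]
        ref = NormalizationReference.from_cohort(basis)
    scaled = (aps - ref.aps_min) / (ref.aps_max - ref.aps_min)
    out_of_range = int(((scaled < 0) | (scaled > 1)).sum())
    if out_of_range:
        logger.info(
            "normalize_aps: %d sample(s) outside the %s reference range, clipped",
            out_of_range,
            ref.source,
        )
    scaled = scaled.clip(0.0, 1.0)
    if b2m_flags is not None:
        flags = b2m_flags.reindex(scaled.index).fillna(False).astype(bool)
        scaled[flags] = 0.0
    return scaled.rename("aps_normalized")


def compute_tigs(aps_normalized: pd.Series, tmb: pd.Series) -> pd.Series:
    """TIGS = APS_normalized x ln(TMB + 1), elementwise over aligned samples."""
    if len(aps_normalized) != len(tmb):
        raise ValueError("aps_normalized and tmb must be sample-aligned")
    tmb_v = np.asarray(tmb, dtype=float)
    if np.any(tmb_v < 0):
        raise ValueError("tmb must be >= 0")
    values = np.asarray(aps_normalized, dtype=float) * np.log1p(tmb_v)
    return pd.Series(values, index=aps_normalized.index, name="tigs")


def standardized_mean(df: pd.DataFrame) -> pd.Series:
    """Per-column mean of row-wise z-scores (mean 0, sd 1 across columns,
    n-denominator).  Zero-variance rows are dropped with a warning."""
    sd = df.std(axis=1, ddof=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"IIS: dropping zero-variance cell-type rows {list(df.index[dead])}"
        )
        df = df[~dead]
        sd = sd[~dead]
        if df.empty:
            raise ValueError("all cell-type score rows have zero variance")
    z = df.sub(df.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0)


def compute_iis(
    expr: ExpressionMatrix,
    cell_type_sets: list[GeneSet] | None = None,
    params: GsvaParams | None = None,
) -> pd.Series:
    """Immune infiltration score: enrichment-score every cell-type marker
    list, z-score each across samples, and average the standardized rows
    per sample (see :func:`standardized_mean`)."""
    cell_type_sets = cell_type_sets or synthetic_immune_cell_sets()
    sm = gsva_scores(expr, cell_type_sets, params)
    if not sm.set_names:
        raise ValueError("no cell-type set could be scored")
    return standardized_mean(sm.to_frame()).rename("iis")


def score_biomarker_panel(
    expr: ExpressionMatrix,
    muts: MutationTable,
    *,
    apm_set: GeneSet | None = None,
    cell_type_sets: list[GeneSet] | None = None,
    signature_sets: dict[str, GeneSet] | None = None,
    params: GsvaParams | None = None,
    ref: NormalizationReference | None = None,
    exome_size_mb: float = DEFAULT_EXOME_SIZE_MB,
    seed: int | None = None,
    n_random_repeats: int = 100,
    tide: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every biomarker for the samples shared by expression and
    mutation data.

    Returns ``(result, apsr)``: ``result`` has one row per shared sample
    with columns aps, aps_normalized, tmb, n_nonsynonymous, b2m_lof,
    tigs, iis, ifng, cd8, pdl1, ifng_gs, isg_rs (and tide when a
    precomputed column is supplied); ``apsr`` holds the random-gene
    negative-control scores, one row per repeat.  Samples present on only
    one side are reported and excluded.
    """
    params = params or GsvaParams()
    apm_set = apm_set or apm_gene_set()
    signature_sets = signature_sets or expression_signature_sets()

    expr_samples = set(expr.sample_ids)
    mut_samples = set(muts.sample_ids)
    shared = [s for s in expr.sample_ids if s in mut_samples]
    if not shared:
        raise ValueError("expression and mutation data share no samples")
    only_expr = sorted(expr_samples - mut_samples)
    only_mut = sorted(mut_samples - expr_samples)
    if only_expr or only_mut:
        logger.info(
            "sample intersection: %d shared; %d expression-only, %d mutation-only",
            len(shared),
            len(only_expr),
            len(only_mut),
        )

    expr_df = expr.to_frame()[shared]
    expr_shared = ExpressionMatrix.from_frame(expr_df)

    aps = compute_aps(expr_shared, apm_set, params)
    nonsyn = filter_nonsynonymous(muts)
    tmb = compute_tmb(nonsyn, shared, exome_size_mb)
    b2m = detect_b2m_lof(muts, shared)
    aps_norm = normalize_aps(aps, ref, b2m)
    tigs = compute_tigs(aps_norm, tmb.tmb_series())
    try:
        iis = compute_iis(expr_shared, cell_type_sets, params)
    except ValueError as e:
        warnings.warn(f"IIS not computed: {e}")
        iis = pd.Series(np.nan, index=shared, name="iis")

    result = pd.DataFrame(
        {
            "aps": aps,
            "aps_normalized": aps_norm,
            "n_nonsynonymous": tmb.to_frame()["n_nonsynonymous"],
            "tmb": tmb.tmb_series(),
            "b2m_lof": b2m,
            "tigs": tigs,
            "iis": iis,
        }
    )
    for key, gene_set in signature_sets.items():
        try:
            result[key] = mean_signature_score(expr_shared, gene_set)
        except ValueError:
            warnings.warn(f"signature {gene_set.name!r} has no genes in the matrix")
            result[key] = np.nan
    if tide is not None:
        result["tide"] = tide.reindex(result.index)

    try:
        apsr = random_control_scores(
            expr_shared,
            n_genes=len(apm_set),
            n_repeats=n_random_repeats,
            seed=seed,
            exclude=apm_set,
            params=params,
        )
    except ValueError as e:
        warnings.warn(f"random-gene control not computed: {e}")
        apsr = []
    apsr_df = pd.DataFrame(
        [s.values for s in apsr],
        index=[f"apsr_{i}" for i in range(len(apsr))],
        columns=shared if apsr else [],
    )
    result.index.name = "sample_id"
    return result, apsr_df
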