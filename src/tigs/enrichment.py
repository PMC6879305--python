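"""Single-sample gene-set enrichment in the GSVA style.

The scorer estimates, per gene, a Gaussian-kernel cumulative density of
each sample's expression against that gene's cross-sample distribution
(bandwidth = sample standard deviation / 4), ranks genes within each
sample by the transformed statistic, and runs a weighted Kolmogorov-
Smirnov-like random walk down the ranking: in-set genes step up in
proportion to their rank weight ``|p/2 - k|^tau``, out-of-set genes step
down by ``1/(p - m)``.  The enrichment score is the magnitude difference
between the walk's largest positive and largest negative deviations, so
every score lies in [-1, 1].

The same engine drives the antigen-presentation score (APS), the immune
infiltration score, and the 18-random-gene negative control; simple
mean-expression signatures (IFNG, CD8, PDL1, ...) are scored directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io_formats import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


@dataclass
class GsvaParams:
    """Tuning knobs for the enrichment scorer.

    kernel : only "gaussian" is implemented (continuous log-scale input;
        the count-data Poisson kernel is out of scope).
    tau : exponent on the symmetric rank weight, default 1.
    es_mode : only "magnitude_difference" (largest positive plus largest
        negative walk deviation, the mode whose scores span [-1, 1]).
    bandwidth_factor : per-gene kernel bandwidth as a fraction of the
        gene's cross-sample standard deviation, default 1/4.
    bandwidth_floor : lower bound on the bandwidth so zero-variance genes
        stay scoreable.
    min_set_genes_present : sets with fewer members present in the matrix
        are skipped with a warning.
    """

    kernel: str = "gaussian"
    tau: float = 1.0
    es_mode: str = "magnitude_difference"
    bandwidth_factor: float = 0.25
    bandwidth_floor: float = 1e-8
    min_set_genes_present: int = 2

    def __post_init__(self) -> None:
        if self.kernel != "gaussian":
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.es_mode != "magnitude_difference":
            raise ValueError(f"unsupported es_mode {self.es_mode!r}")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.bandwidth_factor <= 0:
            raise ValueError("bandwidth_factor must be > 0")


@dataclass
class ScoreMatrix:
    """Gene sets x samples matrix of enrichment scores, each in [-1, 1]."""

    set_names: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValueError("score matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.set_names, columns=self.sample_ids)

    def row(self, name: str) -> pd.Series:
        return self.to_frame().loc[name]


def kernel_cdf_transform(expr: ExpressionMatrix, params: GsvaParams | None = None) -> np.ndarray:
    """Gaussian-kernel CDF estimate of each entry against its gene's
    cross-sample distribution.

    Entry (i, j) is ``mean_k Phi((x_ij - x_ik) / h_i)`` with bandwidth
    ``h_i = bandwidth_factor * sd_i`` (sd with n-1 denominator), floored
    for zero-variance genes.  Requires >= 2 samples.
    """
    params = params or GsvaParams()
    x = expr.values
    p, n = x.shape
    if n < 2:
        raise ValueError(
            "kernel CDF estimation needs >= 2 samples: the statistic is the "
            "position of each sample within the gene's cross-sample distribution"
        )
    sd = x.std(axis=1, ddof=1)
    h = np.maximum(params.bandwidth_factor * sd, params.bandwidth_floor)
    out = np.empty_like(x)
    for i in range(p):  # per-gene loop keeps peak memory at O(n^2)
        diff = (x[i, :, None] - x[i, None, :]) / h[i]
        out[i] = ndtr(diff).mean(axis=1)
    return out


def _rank_weights(p: int, tau: float) -> np.ndarray:
    # weight of the gene at 1-based rank position k (ranked by decreasing
    # transformed statistic)
    k = np.arange(1, p + 1, dtype=float)
    return np.abs(p / 2.0 - k) ** tau


def rank_walk_scores(
    transformed: np.ndarray,
    gene_ids: list[str],
    sample_ids: list[str],
    sets: list[GeneSet],
    params: GsvaParams | None = None,
) -> ScoreMatrix:
    """Score gene sets against a kernel-CDF-transformed matrix.

    Per sample, genes are ordered by decreasing transformed statistic
    (ties broken by stable input order); the walk increments by the gene's
    normalized rank weight for in-set genes and decrements by ``1/(p-m)``
    otherwise.  Score = largest positive deviation + largest negative
    deviation (the negative one is <= 0).
    """
    params = params or GsvaParams()
    transformed = np.asarray(transformed, dtype=float)
    p, n = transformed.shape
    if p != len(gene_ids):
        raise ValueError("gene_ids length does not match matrix rows")

    # gene index at each rank position, per sample (stable => deterministic ties)
    order = np.argsort(-transformed, axis=0, kind="stable")
    w = _rank_weights(p, params.tau)

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    names: list[str] = []
    rows: list[np.ndarray] = []
    for s in sets:
        present = [g for g in s.genes if g in gene_index]
        missing = len(s.genes) - len(present)
        if missing:
            warnings.warn(
                f"gene set {s.name!r}: {missing} gene(s) absent from the matrix"
            )
        m = len(present)
        if m < params.min_set_genes_present:
            warnings.warn(
                f"gene set {s.name!r} skipped: only {m} member(s) present "
                f"(min_set_genes_present={params.min_set_genes_present})"
            )
            continue
        if m == p:
            raise ValueError(
                f"cannot score a set equal to the gene universe ({s.name!r})"
            )
        member = np.zeros(p, dtype=bool)
        member[[gene_index[g] for g in present]] = True

        inset = member[order]                      # (p positions) x (n samples)
        win = np.where(inset, w[:, None], 0.0)
        denom = win.sum(axis=0)
        steps = win / denom - (~inset) / (p - m)
        walk = np.cumsum(steps, axis=0)
        es = np.maximum(walk.max(axis=0), 0.0) + np.minimum(walk.min(axis=0), 0.0)
        names.append(s.name)
        rows.append(es)
    values = np.vstack(rows) if rows else np.empty((0, n))
    return ScoreMatrix(names, list(sample_ids), values)


def gsva_scores(
    expr: ExpressionMatrix, sets: list[GeneSet], params: GsvaParams | None = None
) -> ScoreMatrix:
    """Full pipeline: kernel CDF transform, then rank-walk scoring."""
    params = params or GsvaParams()
    transformed = kernel_cdf_transform(expr, params)
    return rank_walk_scores(transformed, expr.gene_ids, expr.sample_ids, sets, params)


def mean_signature_score(expr: ExpressionMatrix, gene_set: GeneSet) -> pd.Series:
    """Per-sample arithmetic mean of the expression of the set genes
    present in the matrix (the convention for IFNG/CD8/PDL1-style
    published signatures)."""
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    idx = [gene_index[g] for g in gene_set.genes if g in gene_index]
    n_missing = len(gene_set.genes) - len(idx)
    if not idx:
        raise ValueError(
            f"no gene of signature {gene_set.name!r} is present in the matrix"
        )
    if n_missing:
        warnings.warn(
            f"signature {gene_set.name!r}: {n_missing} of {len(gene_set.genes)} "
            "genes absent; mean taken over present genes"
        )
    return pd.Series(
        expr.values[idx].mean(axis=0), index=expr.sample_ids, name=gene_set.name
    )


def random_control_scores(
    expr: ExpressionMatrix,
    n_genes: int = 18,
    n_repeats: int = 100,
    seed: int | None = None,
    exclude: GeneSet | None = None,
    params: GsvaParams | None = None,
) -> list[pd.Series]:
    """Negative-control enrichment: ``n_repeats`` random gene sets of size
    ``n_genes`` drawn without replacement from genes outside ``exclude``
    (by default the antigen-presentation list is what callers exclude),
    each scored by the rank-walk engine.  Reproducible under ``seed``."""
    params = params or GsvaParams()
    excluded = set(exclude.genes) if exclude is not None else set()
    eligible = [g for g in expr.gene_ids if g not in excluded]
    if len(eligible) <= n_genes:
        raise ValueError(
            f"need more than {n_genes} eligible genes outside the exclusion "
            f"set, have {len(eligible)}"
        )
    rng = np.random.default_rng(seed)
    transformed = kernel_cdf_transform(expr, params)
    out: list[pd.Series] = []
    for r in range(n_repeats):
        drawn = list(rng.choice(eligible, size=n_genes, replace=False))
        sm = rank_walk_scores(
            transformed,
            expr.gene_ids,
            expr.sample_ids,
            [GeneSet(f"random_{r}", drawn)],
            params,
        )
        s = sm.to_frame().iloc[0]
        s.attrs["genes"] = drawn
        out.append(s)
    return out
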