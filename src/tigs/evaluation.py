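"""Biomarker evaluation: ROC/AUC, median-split survival, and the
cohort-level objective-response-rate (ORR) linear model.

Individual-patient predictive power is measured by the area under the
empirical ROC curve (equivalently the Mann-Whitney concordance
probability, ties counted half).  Survival separation uses the field's
standard design: split at the cohort median (strictly above = High),
Kaplan-Meier curves per group, unweighted two-group log-rank test.  At
the cohort level, pooled ORR (percent) is regressed by ordinary least
squares on the median biomarker value across tumor types, yielding
prediction formulas of the form ``ORR = slope x TIGS + intercept``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .io_formats import ClinicalTable


@dataclass
class RocResult:
    """Empirical ROC curve and its area."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def roc_auc(
    scores: Sequence[float] | pd.Series,
    labels: Sequence[float] | pd.Series,
    *,
    higher_is_positive: bool = True,
) -> RocResult:
    """ROC over all observed thresholds; AUC by the trapezoid rule,
    identical to concordant-pair counting with ties counted half.

    ``labels`` are binary (1 = responder).  Pairs with a missing score or
    label are dropped.  Set ``higher_is_positive=False`` for biomarkers
    where a LOW value predicts response (e.g. an ingested TIDE column).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    keep = ~(np.isnan(s) | np.isnan(y))
    s, y = s[keep], y[keep]
    if not higher_is_positive:
        s = -s
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        missing = "positive (responder)" if n_pos == 0 else "negative (non-responder)"
        raise ValueError(f"ROC needs both classes; no {missing} labels present")
    fpr, tpr, thr = _roc_curve(y, s)
    return RocResult(thr, fpr, tpr, float(_trapezoid_auc(fpr, tpr)), n_pos, n_neg)


def median_split(scores: pd.Series | Sequence[float]) -> pd.Series:
    """Label samples 'High' (strictly above the cohort median) or 'Low'
    (at or below, including ties at the median).

    All-identical scores give an all-Low degenerate split (warned)."""
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("median split needs >= 2 samples")
    med = s.median()
    labels = pd.Series(np.where(s > med, "High", "Low"), index=s.index, name="group")
    if (labels == "Low").all():
        warnings.warn("degenerate median split: no sample strictly above the median")
    return labels


@dataclass
class KmLogrankResult:
    """Kaplan-Meier curves per group plus the two-group log-rank test."""

    survival: dict[str, pd.DataFrame]
    statistic: float
    p_value: float
    group_sizes: dict[str, int]

    def survival_at(self, group: str, t: float) -> float:
        """Product-limit survival estimate for ``group`` at time ``t``."""
        sf = self.survival[group]
        past = sf[sf.index <= t]
        return 1.0 if past.empty else float(past.iloc[-1, 0])


def km_logrank(groups: pd.Series, clinical: ClinicalTable) -> KmLogrankResult:
    """Product-limit survival per group and the unweighted two-group
    log-rank statistic with its two-sided p-value.

    ``groups`` maps sample id -> group label (typically from
    :func:`median_split`); samples missing survival data are removed.
    """
    clin = clinical.to_frame()
    df = pd.DataFrame({"group": groups}).join(clin[["os_time", "os_event"]], how="inner")
    df = df.dropna(subset=["group", "os_time", "os_event"])
    names = sorted(df["group"].unique())
    if len(names) != 2:
        raise ValueError(
            f"log-rank comparison needs exactly 2 non-empty groups, got {names}"
        )
    parts = {g: df[df["group"] == g] for g in names}
    for g, part in parts.items():
        if part.empty:
            raise ValueError(f"group {g!r} is empty after missing-data removal")
        if (part["os_event"] == 1).sum() == 0:
            warnings.warn(f"group {g!r} has no observed events")
    survival: dict[str, pd.DataFrame] = {}
    for g, part in parts.items():
        kmf = KaplanMeierFitter()
        kmf.fit(part["os_time"], part["os_event"], label=g)
        survival[g] = kmf.survival_function_
    a, b = (parts[g] for g in names)
    res = logrank_test(a["os_time"], b["os_time"], a["os_event"], b["os_event"])
    return KmLogrankResult(
        survival,
        float(res.test_statistic),
        float(res.p_value),
        {g: len(part) for g, part in parts.items()},
    )


# ---------------------------------------------------------------------------
# Cohort-level ORR model


@dataclass
class CohortORRPoint:
    """One tumor type in the pan-cancer ORR analysis: the pooled objective
    response rate (percent) with the cohort-median biomarker values."""

    tumor_type: str
    orr: float
    median_tigs: float | None = None
    median_tmb: float | None = None
    median_aps_normalized: float | None = None
    n_patients: int = 10
    n_profiled: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.orr <= 100):
            raise ValueError(f"ORR must be a percentage in [0, 100], got {self.orr}")
        if self.n_patients < 10:
            raise ValueError(
                "cohorts with fewer than 10 patients are excluded from the "
                f"ORR analysis ({self.tumor_type}: n={self.n_patients})"
            )


_PREDICTOR_FIELDS = {
    "tigs": "median_tigs",
    "tmb": "median_tmb",
    "aps": "median_aps_normalized",
}


@dataclass
class ORRModel:
    """OLS fit of pooled ORR (percent) on a cohort-median biomarker."""

    slope: float
    intercept: float
    r: float | None = None
    r_squared: float | None = None
    p_value: float | None = None
    resid_se: float | None = None
    spearman_r: float | None = None
    spearman_p: float | None = None
    n: int | None = None
    predictor: str = "tigs"
    # sufficient statistics for the mean-response confidence interval
    _x_mean: float | None = field(default=None, repr=False)
    _sxx: float | None = field(default=None, repr=False)

    @classmethod
    def from_coefficients(
        cls, slope: float, intercept: float, predictor: str = "tigs"
    ) -> "ORRModel":
        """A model instantiated from published coefficients; point
        predictions only (no confidence interval without the fit data)."""
        return cls(slope=slope, intercept=intercept, predictor=predictor)


def fit_orr_model(
    points: Sequence[CohortORRPoint] | pd.DataFrame,
    predictor: str = "tigs",
) -> ORRModel:
    """Ordinary least squares of ORR (percent) on a cohort-median
    predictor, with Pearson and Spearman correlations.

    Needs >= 3 points with non-zero predictor variance.  ``points`` may
    also be a DataFrame with columns ``orr`` and ``median_<predictor>``.
    """
    if predictor not in _PREDICTOR_FIELDS:
        raise ValueError(f"predictor must be one of {sorted(_PREDICTOR_FIELDS)}")
    col = _PREDICTOR_FIELDS[predictor]
    if isinstance(points, pd.DataFrame):
        df = points[["orr", col]].dropna()
        x = df[col].to_numpy(dtype=float)
        y = df["orr"].to_numpy(dtype=float)
    else:
        pairs = [(getattr(p, col), p.orr) for p in points if getattr(p, col) is not None]
        x = np.array([a for a, _ in pairs], dtype=float)
        y = np.array([b for _, b in pairs], dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"ORR regression needs >= 3 cohort points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance across cohorts")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    resid_se = float(np.sqrt(np.sum(resid**2) / (n - 2)))
    rho, rho_p = stats.spearmanr(x, y)
    return ORRModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        resid_se=resid_se,
        spearman_r=float(rho),
        spearman_p=float(rho_p),
        n=n,
        predictor=predictor,
        _x_mean=float(x.mean()),
        _sxx=float(np.sum((x - x.mean()) ** 2)),
    )


def predict_orr(
    model: ORRModel, value: float, alpha: float = 0.05
) -> tuple[float, tuple[float, float] | None]:
    """Predicted ORR (percent) at a biomarker value, with the standard
    95% confidence interval for the mean response when the model carries
    its fit statistics (coefficient-only models yield no interval)."""
    point = model.slope * value + model.intercept
    if model.resid_se is None or model._sxx is None or model.n is None:
        return point, None
    se = model.resid_se * np.sqrt(1 / model.n + (value - model._x_mean) ** 2 / model._sxx)
    tq = stats.t.ppf(1 - alpha / 2, model.n - 2)
    return point, (point - tq * se, point + tq * se)


def slope_confidence_interval(model: ORRModel, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided confidence interval for the fitted slope."""
    if model.resid_se is None or model._sxx is None or model.n is None:
        raise ValueError("model carries no fit statistics")
    se = model.resid_se / np.sqrt(model._sxx)
    tq = stats.t.ppf(1 - alpha / 2, model.n - 2)
    return model.slope - tq * se, model.slope + tq * se


# ---------------------------------------------------------------------------
# Biomarker ladder


#: Biomarkers where a LOW value predicts response (negated before ROC).
LOWER_IS_RESPONSE = frozenset({"tide"})

_LADDER_COLUMNS = [
    "tigs",
    "tmb",
    "aps",
    "aps_normalized",
    "iis",
    "ifng",
    "cd8",
    "pdl1",
    "ifng_gs",
    "isg_rs",
    "tide",
]


def compare_biomarkers(
    result: pd.DataFrame,
    labels: pd.Series,
    apsr_scores: pd.DataFrame | None = None,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One AUC per biomarker column (each on its own non-missing subset,
    with n reported), plus the mean AUC over the random-gene control
    repeats when ``apsr_scores`` is given.

    ``labels`` is the binary responder label indexed by sample;
    orientation follows :data:`LOWER_IS_RESPONSE`.
    """
    if columns is None:
        columns = [c for c in _LADDER_COLUMNS if c in result.columns]
    labels = labels.reindex(result.index)
    rows = []
    for col in columns:
        scores = result[col]
        keep = scores.notna() & labels.notna()
        r = roc_auc(
            scores[keep], labels[keep], higher_is_positive=col not in LOWER_IS_RESPONSE
        )
        rows.append({"biomarker": col, "auc": r.auc, "n": r.n_positive + r.n_negative})
    if apsr_scores is not None and len(apsr_scores):
        aucs = []
        for _, row in apsr_scores.iterrows():
            s = row.reindex(result.index)
            keep = s.notna() & labels.notna()
            aucs.append(roc_auc(s[keep], labels[keep]).auc)
        rows.append(
            {
                "biomarker": "apsr",
                "auc": float(np.mean(aucs)),
                "n": int(keep.sum()),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("auc", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
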