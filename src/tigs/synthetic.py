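"""Seeded synthetic immunotherapy cohorts for end-to-end testing.

The generator emulates the statistical structure the scoring method
assumes in real data:

* a latent antigen-presentation factor loading on the 18 APM genes,
  correlated (configurably) with a latent immune-infiltration factor
  that drives the immune cell-type and interferon signature genes;
* approximately Gaussian log tumor mutational burden (per-sample
  mutation counts drawn log-normally and materialized as MAF records
  with a fixed mix of synonymous and non-synonymous classes, plus
  optional B2M loss-of-function events);
* response probability increasing logistically with the true
  immunogenicity score; and
* exponential overall survival whose hazard decreases with the true
  score, under independent censoring.

A truth table records the latent factors and noise-free scores so that
recovery by the estimation pipeline can be measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
import pandas as pd

from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    MutationRecord,
    MutationTable,
)
from .signatures import (
    APM_GENES,
    CD8_GENES,
    IFNG_GENES,
    PDL1_GENES,
    expression_signature_sets,
    synthetic_immune_cell_sets,
)

#: MAF class mix used when materializing mutation records.  Fixed so the
#: non-synonymous filter has deterministic expectations: 80% of records
#: are non-synonymous (missense + nonsense + frameshift).
MAF_CLASS_FREQUENCIES: dict[str, float] = {
    "Missense_Mutation": 0.60,
    "Nonsense_Mutation": 0.10,
    "Silent": 0.10,
    "Frame_Shift_Ins": 0.05,
    "Frame_Shift_Del": 0.05,
    "Intron": 0.05,
    "3'UTR": 0.05,
}

_NONSYN_IN_MIX = {
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
}


@dataclass
class CohortSimParams:
    """Knobs of the cohort generator (defaults are the study conditions
    used throughout the test suite).

    n_samples, n_genes : cohort dimensions; the gene budget must cover
        the named signature genes (error otherwise).
    apm_factor_sd : scale of the latent antigen-presentation factor.
    apm_loading : loading of the 18 APM genes on that factor.
    iis_apm_correlation : correlation between the immune-infiltration
        and antigen-presentation latent factors.
    immune_loading : loading of immune cell-type / interferon genes on
        the infiltration factor.
    noise_sd : per-gene residual expression noise (log-scale units).
    tmb_log_mean, tmb_log_sd : log-normal TMB (mutations/Mb): ln TMB ~
        Normal(tmb_log_mean, tmb_log_sd).
    response_slope, response_intercept : logistic link from true TIGS to
        response probability.
    surv_base_rate : exponential event hazard at TIGS = 0 (per study
        time unit).
    surv_tigs_effect : log-hazard decrease per TIGS unit (higher
        immunogenicity, better survival under therapy).
    censor_rate : target fraction censored (independent exponential
        censoring).
    b2m_lof_prob : probability a sample carries an injected B2M
        loss-of-function record.
    full_signature_panel : include the immune cell-type and interferon
        signature placeholder genes (needed for IIS); switch off for
        minimal fixtures.
    """

    n_samples: int = 200
    n_genes: int = 400
    apm_factor_sd: float = 1.0
    apm_loading: float = 1.0
    iis_apm_correlation: float = 0.7
    immune_loading: float = 1.0
    noise_sd: float = 1.0
    tmb_log_mean: float = 1.0
    tmb_log_sd: float = 1.5
    response_slope: float = 2.0
    response_intercept: float = -2.0
    surv_base_rate: float = 0.05
    surv_tigs_effect: float = 0.5
    censor_rate: float = 0.3
    b2m_lof_prob: float = 0.05
    exome_size_mb: float = 38.0
    full_signature_panel: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("apm_factor_sd", "noise_sd", "tmb_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("censor_rate", "b2m_lof_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not -1 <= self.iis_apm_correlation <= 1:
            raise ValueError("iis_apm_correlation must be in [-1, 1]")


def _gene_universe(params: CohortSimParams) -> tuple[list[str], dict[str, str]]:
    """Ordered gene symbols plus a gene -> latent-factor role map."""
    role: dict[str, str] = {}
    for g in APM_GENES:
        role[g] = "apm"
    immune_genes: list[str] = []
    immune_genes += [g for g in IFNG_GENES + CD8_GENES + PDL1_GENES]
    if params.full_signature_panel:
        for s in synthetic_immune_cell_sets():
            immune_genes += s.genes
        sigs = expression_signature_sets()
        immune_genes += sigs["ifng_gs"].genes + sigs["isg_rs"].genes
    for g in immune_genes:
        role.setdefault(g, "immune")
    named = list(role)
    if params.n_genes < len(named):
        raise ValueError(
            f"infeasible gene budget: n_genes={params.n_genes} but the "
            f"signature panel needs {len(named)} named genes"
        )
    fillers = [f"GENE_{i:04d}" for i in range(1, params.n_genes - len(named) + 1)]
    for g in fillers:
        role[g] = "noise"
    return named + fillers, role


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    params: CohortSimParams,
) -> tuple[ExpressionMatrix, MutationTable, ClinicalTable, pd.DataFrame]:
    """Simulate one cohort.

    Returns (expression, mutations, clinical, truth); byte-identical
    for identical parameters (the seed lives in ``params``).
    """
    rng = np.random.default_rng(params.seed)
    genes, role = _gene_universe(params)
    n, p = params.n_samples, params.n_genes
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    # latent factors: apm factor a, immune factor u with corr rho
    a = rng.normal(0.0, params.apm_factor_sd, size=n)
    rho = params.iis_apm_correlation
    u = rho * (a / params.apm_factor_sd) + np.sqrt(1 - rho**2) * rng.normal(size=n)

    baseline = rng.normal(6.0, 1.5, size=p)
    x = baseline[:, None] + rng.normal(0.0, params.noise_sd, size=(p, n))
    for i, g in enumerate(genes):
        if role[g] == "apm":
            x[i] += params.apm_loading * a
        elif role[g] == "immune":
            x[i] += params.immune_loading * u
    expr = ExpressionMatrix(genes, samples, x)

    # mutations: log-normal TMB target, materialized as MAF records
    tmb_target = np.exp(rng.normal(params.tmb_log_mean, params.tmb_log_sd, size=n))
    classes = list(MAF_CLASS_FREQUENCIES)
    freqs = np.array([MAF_CLASS_FREQUENCIES[c] for c in classes])
    nonsyn_frac = sum(MAF_CLASS_FREQUENCIES[c] for c in _NONSYN_IN_MIX)
    mut_genes = [g for g in genes if g != "B2M"]  # no accidental B2M hits
    b2m_lof = rng.random(n) < params.b2m_lof_prob
    records: list[MutationRecord] = []
    realized_nonsyn = np.zeros(n, dtype=int)
    for j, s in enumerate(samples):
        total = int(round(tmb_target[j] * params.exome_size_mb / nonsyn_frac))
        counts = rng.multinomial(total, freqs)
        for cls, c in zip(classes, counts):
            if c == 0:
                continue
            for g in rng.choice(mut_genes, size=c):
                records.append(MutationRecord(s, str(g), cls))
            if cls in _NONSYN_IN_MIX:
                realized_nonsyn[j] += c
        if b2m_lof[j]:
            records.append(MutationRecord(s, "B2M", "Nonsense_Mutation"))
            realized_nonsyn[j] += 1
    muts = MutationTable(records)

    true_tmb = realized_nonsyn / params.exome_size_mb
    true_aps_norm = _sigmoid(a)
    true_aps_norm[b2m_lof] = 0.0
    true_tigs = true_aps_norm * np.log1p(true_tmb)

    resp_prob = _sigmoid(params.response_intercept + params.response_slope * true_tigs)
    response = (rng.random(n) < resp_prob).astype(float)

    event_rate = params.surv_base_rate * np.exp(-params.surv_tigs_effect * true_tigs)
    t_event = rng.exponential(1.0 / event_rate)
    if params.censor_rate > 0:
        cens_rate = (
            params.censor_rate / (1 - params.censor_rate) * params.surv_base_rate
            if params.censor_rate < 1
            else np.inf
        )
        t_cens = rng.exponential(1.0 / cens_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(float)

    clinical = ClinicalTable(samples, response, os_time, os_event)
    truth = pd.DataFrame(
        {
            "apm_factor": a,
            "immune_factor": u,
            "true_aps_normalized": true_aps_norm,
            "true_tmb": true_tmb,
            "true_tigs": true_tigs,
            "b2m_lof": b2m_lof,
            "response_prob": resp_prob,
            "response": response,
            "os_time": os_time,
            "os_event": os_event,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return expr, muts, clinical, truth


#: Parameters of the small bundled worked-example cohort.
WORKED_FIXTURE_PARAMS = CohortSimParams(
    n_samples=12,
    n_genes=30,
    tmb_log_mean=1.2,
    tmb_log_sd=0.8,
    b2m_lof_prob=0.12,
    full_signature_panel=False,
    seed=12,
)


def worked_fixture() -> tuple[ExpressionMatrix, MutationTable, ClinicalTable, pd.DataFrame]:
    """The deterministic 30-gene x 12-sample worked-example cohort whose
    APS/TMB/TIGS/AUC values are committed as regression goldens
    (computed once by independent reference implementations)."""
    return generate_cohort(WORKED_FIXTURE_PARAMS)


def worked_fixture_goldens() -> dict:
    """Committed reference values for the worked fixture."""
    text = (
        resources.files("tigs").joinpath("data/worked_fixture_goldens.json").read_text()
    )
    return json.loads(text)


def params_to_dict(params: CohortSimParams) -> dict:
    return asdict(params)
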