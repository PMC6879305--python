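# tigs — tumor immunogenicity scoring for immunotherapy response prediction

Only a minority of cancer patients respond to immune checkpoint
inhibitors (ICI), and tumor mutational burden (TMB) alone is an
imperfect predictor: a tumor must both *carry* antigens and *present*
them on MHC class I for T cells to act.  `tigs` implements a
tumor-inherent biomarker that combines both determinants:

* **APS** — the antigen processing and presenting machinery (APM)
  score: a single-sample, GSVA-style enrichment score (in [−1, 1]) of an
  18-gene MHC class I pathway list (*PSMB5–10, TAP1/2, ERAP1/2, CANX,
  CALR, PDIA3, TAPBP, B2M, HLA-A/B/C*) computed from a log-scale
  expression matrix.
* **TMB** — non-synonymous somatic mutations per megabase, from a MAF
  mutation table with a 38 Mb whole-exome size.
* **TIGS** — the tumor immunogenicity score

  `TIGS = APS_normalized × ln(TMB + 1)`

  where `APS_normalized = (APS − APS_min) / (APS_max − APS_min)` ∈ [0, 1]
  (cohort-derived or user-supplied pan-cancer reference) and is forced
  to 0 for tumors carrying a B2M loss-of-function mutation, which
  abolishes MHC class I surface presentation regardless of expression.

The package also scores the comparator biomarker panel used to
benchmark ICI-response predictors — IIS (immune infiltration score:
mean of across-sample-standardized immune cell-type enrichment
scores), IFNG / CD8 / PDL1 / IFNG.GS / ISG.RS mean-expression
signatures, and the APSr random-18-gene negative control — and provides
the evaluation layer: ROC/AUC ladders, median-split Kaplan–Meier
survival with the log-rank test, and the cohort-level linear model of
pooled objective response rate (ORR, percent) on median TIGS, including
point predictions such as `ORR = 21.4 × TIGS − 2.7`.

It is aimed at computational oncologists evaluating ICI-response
biomarkers on cohorts with paired expression, mutation and clinical
outcome data, and ships a seeded synthetic-cohort generator so every
stage is testable without downloads.

## Worked example

Simulate a 200-patient cohort, score it, and rank the biomarkers:

```bash
tigs simulate --seed 42 --out-dir demo
tigs score --expr demo/expr.tsv --maf demo/muts.maf --seed 42 --out demo/scores.tsv
tigs evaluate --scores demo/scores.tsv --clinical demo/clinical.tsv \
              --apsr demo/scores.apsr.tsv --out demo/auc.tsv --km-out demo/km.tsv
```

which prints the AUC ladder for predicting responders:

```
     biomarker      auc   n
          tigs 0.809420 200
aps_normalized 0.727150 200
           tmb 0.723052 200
           aps 0.679012 200
           cd8 0.528167 200
          ifng 0.518104 200
        isg_rs 0.513954 200
       ifng_gs 0.501919 200
          pdl1 0.501816 200
           iis 0.500052 200
          apsr 0.482526 200
```

TIGS (AUC 0.81) outperforms its own components — normalized APS (0.73)
and TMB (0.72) — because the simulated response is driven by their
product, while the random-gene control APSr sits at chance (0.48).  The
first rows of `demo/scores.tsv` (signature columns abridged):

```
sample_id    aps  aps_normalized  n_nonsynonymous    tmb  b2m_lof  tigs
    S0001  0.171           0.632              227  5.974    False 1.227
    S0002 -0.590           0.146               38  1.000    False 0.101
    S0003  0.479           0.828              440 11.579    False 2.097
```

e.g. S0003 combines high antigen presentation (normalized APS 0.83)
with 11.6 mutations/Mb into TIGS = 0.828 × ln(12.58) = 2.10.  The
median-split log-rank summary (`demo/km.tsv`) compares overall survival
between TIGS-High and TIGS-Low patients (here χ² = 2.52, p = 0.11 for
TIGS vs χ² = 1.93, p = 0.16 for TMB at n = 200).

Cohort-level ORR modeling:

```bash
tigs orr-fit --table orr_points.tsv --predict 0.7
# predicted ORR at tigs=0.7: 12.3% (...)
```

The same functionality is available as a library
(`tigs.compute_aps`, `tigs.compute_tigs`, `tigs.score_biomarker_panel`,
`tigs.fit_orr_model`, ...) and as a config-driven pipeline (`tigs run
--config run.yaml`).

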