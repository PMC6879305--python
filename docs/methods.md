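# Methods

## The scoring model

Tumor immunogenicity is modeled as the product of two tumor-inherent
determinants: tumor antigenicity and antigen presentation efficiency.

**Antigen presentation (APS).**  The expression of the 18 MHC class I
antigen processing and presenting machinery genes (proteasome and
immunoproteasome subunits, TAP transporters, ERAP aminopeptidases, ER
chaperones, TAPBP, B2M, HLA-A/B/C) is summarized per sample by a
GSVA-style enrichment statistic:

1. *Kernel CDF transform.*  For gene *i* with expression `x_i1..x_in`
   across *n* samples, each entry is replaced by its Gaussian-kernel
   estimated cumulative density,
   `ẑ_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i)` with bandwidth
   `h_i = s_i/4` (cross-sample standard deviation, n−1 denominator).
   This puts genes with different dynamic ranges on a comparable scale
   while preserving each sample's position within the gene's
   distribution.  It assumes continuous log-scale input (normalized
   RNA-seq or microarray); a count-data kernel is deliberately not
   implemented.
2. *Rank walk.*  Per sample, all *p* genes are ordered by decreasing
   transformed statistic; the gene at rank *k* carries the symmetric
   weight `|p/2 − k|^τ` (τ = 1).  A walk over the ranking steps up by
   the gene's weight (normalized by the total in-set weight) for the
   *m* set genes and down by `1/(p − m)` otherwise.  The enrichment
   score is the **magnitude difference**: the walk's largest positive
   deviation plus its largest negative deviation (the latter ≤ 0).
   Both deviations are differences of two ECDF-like quantities in
   [0, 1], so every score lies in [−1, 1].

**Normalization.**  `APS_normalized = (APS − APS_min)/(APS_max −
APS_min)`.  The reference is either user-supplied (e.g. a pan-cancer
min/max, for cross-cohort comparability; out-of-range cohort values are
clipped and logged) or cohort-derived.  A cohort-derived reference is
computed over B2M-wild-type samples: flagged samples are overridden to
0 anyway, so letting a B2M-mutant extreme set the range would shrink
every other sample's scale.  Normalization happens first, the B2M
override second.

**B2M loss of function.**  Samples with ≥ 1 B2M record in a truncating
class ({Nonsense, Frame_Shift_Ins/Del, Splice_Site, Nonstop,
Translation_Start_Site}) get `APS_normalized = 0`: without
beta-2-microglobulin no MHC class I complex reaches the surface,
whatever the pathway's mRNA levels.  The class set is configurable; a
missense B2M variant does not trigger the override.

**Antigenicity (TMB).**  Non-synonymous mutations per megabase, with
the non-synonymous class set {Missense, Nonsense, Nonstop,
Frame_Shift_Ins/Del, In_Frame_Ins/Del, Splice_Site,
Translation_Start_Site} (configurable) and a 38 Mb whole-exome size.
Every qualifying record is counted (multiple hits in one gene count
individually).  Samples enumerated in the cohort but absent from the
mutation table get TMB = 0 with a "no variants observed" flag.

**TIGS.**  `TIGS = APS_normalized × ln(TMB + 1)`.  The pseudo-count
keeps the score defined and non-negative for tumors below one
mutation/Mb; the natural logarithm reflects the empirically linear
relation between log TMB and response rates.  TIGS is 0 whenever
TMB = 0 or the B2M override fires, and is monotone non-decreasing in
each factor.

**Comparator panel.**  IIS is the per-sample mean of across-sample
z-scored (population sd) enrichment scores for a panel of immune
cell-type marker lists; zero-variance cell-type rows are dropped with a
warning.  IFNG ({IFNG, STAT1, IDO1, CXCL10, CXCL9, HLA-DRA}), CD8
({CD8A, CD8B}) and PDL1 ({CD274}) are plain mean-expression scores.
APSr is the negative control: 100 draws of 18 random genes (excluding
the APM list), each scored by the same enrichment engine; its mean AUC
estimates the chance level of the pipeline.  TIDE is never computed —
a precomputed column can be joined, and is negated before ROC because
low TIDE indicates response.

## Evaluation layer

ROC curves are empirical over all observed thresholds; AUC is the
trapezoid area, identical to the Mann–Whitney concordance probability
with ties counted half (asserted against a brute-force pair-counting
oracle in the tests).  Each biomarker is evaluated on its own
non-missing subset with n reported.  Survival comparisons use the
median split (strictly above the cohort median = High; ties at the
median go Low), Kaplan–Meier product-limit curves, and the unweighted
two-group log-rank test, unstratified.  The cohort-level ORR model is
ordinary least squares of pooled ORR (percent) on the cohort-median
predictor, reporting slope, intercept, Pearson r/r², two-sided p,
residual SE and (since rank- and linear-correlation conventions differ
between uses) the Spearman correlation as well; mean-response
confidence intervals use the standard `s·√(1/n + (x₀−x̄)²/Sxx)` formula.
Models can also be instantiated directly from published coefficients,
in which case only point predictions are available.

## Numerical choices

* Rank ties after the CDF transform are broken by stable input gene
  order — deterministic, and measure-zero for continuous data.
* Zero-variance genes get a bandwidth floor of 1e-8 instead of being
  dropped, so constant rows in toy fixtures remain scoreable (their
  transformed row is exactly 1/2).
* Genes in a set but absent from the matrix are dropped with a warning;
  a set is scored only if ≥ 2 members are present, and a set equal to
  the whole gene universe is an error (the walk's down-step is
  undefined).
* Duplicate gene symbols in expression input collapse to the row with
  the highest mean expression by default (the usual multi-probe
  microarray convention); `mean` and `first` rules are available.
  Missing expression values are rejected unless the caller opts into
  dropping incomplete genes; gene symbols match case-sensitively with
  no alias resolution.
* Score tables round-trip value-exactly: shortest-repr floats out,
  `float_precision="round_trip"` parsing in; missing values are empty
  cells, never zero.

## The synthetic cohort generator

`tigs.synthetic.generate_cohort` emulates the features the method
relies on: an APM co-expression block driven by a latent
antigen-presentation factor (loading 1.0, factor sd 1.0), an immune
block (cell-type, interferon, CD8/PDL1 genes) driven by a second factor
correlated at 0.7 with the first, Gaussian residual noise (sd 1.0,
log-scale units), log-normal TMB (`ln TMB ~ N(1.0, 1.5²)`, i.e. a
median near 2.7 mutations/Mb with the order-of-magnitude spread typical
of ICI cohorts), MAF records materialized with a fixed class mix (60%
missense, 10% nonsense, 10% silent, 10% frameshift split Ins/Del, 10%
non-coding; 80% non-synonymous overall), B2M loss-of-function injection
(5%), logistic response in the true score
(`P(response) = σ(−2 + 2·TIGS_true)`, baseline ORR ≈ 12%), and
exponential survival with hazard `0.05·exp(−0.5·TIGS_true)` per study
time unit under independent exponential censoring (≈ 30%).  True TIGS
uses the same `ln(TMB+1)` formula with the noise-free latent factor
squashed to [0, 1] logistically, so truth and estimate are directly
comparable.  The TMB spread was set so the generator's own
discriminability contract holds with margin: at logistic slope 2 and
n = 300 the true-score AUC averages ≈ 0.76 (min ≈ 0.72 over seeds).

What the generator does **not** emulate: real gene–gene covariance
beyond the two-factor structure, cancer-type-specific APS or TMB
distributions, batch effects, purity, or missingness.  Two scaled-down
artifacts follow from the small synthetic transcriptome (hundreds of
genes, vs ~20k in real data): samples can draw zero mutation rows and
then legitimately drop out of the expression∩mutation intersection; and
because enrichment scores are relative ranks, a latent factor moving a
third of all genes induces a compositional anti-correlation in the
remaining genes' scores — so fully decoupling APS from the
presentation factor requires zeroing both its loading and the
factor correlation.  Passing tests on these cohorts demonstrate
correctness of the computations and calibration of the statistics, not
clinical performance on real tumors.

Problem sizes in the test suite (300-sample discrimination cohorts, 200
log-rank null replicates at n = 60, 100 ORR-recovery replicates) were
chosen as the smallest at which the checked statistics are stable.

## Known limitations

* APS is an mRNA-level proxy; protein-level APM function, MHC class II
  presentation, germline antigens, purity and clonality are out of
  scope.
* The enrichment scorer implements the Gaussian-kernel,
  magnitude-difference configuration only; no permutation significance
  or competitive set testing.
* The log-rank test is the unweighted two-group variant; no
  stratification, no Cox modeling, no multi-cohort meta-analysis.
* ORR points must come with ≥ 10 patients per cohort (the inclusion
  rule for pooled response rates); the linear model extrapolates
  outside the fitted TIGS range without warning.
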