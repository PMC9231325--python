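# Methods

## Setting

The package models a retrospective case-control design: cases are subjects
with prediabetes or T2DM (impaired fasting glucose 100–125 mg/dL, fasting
glucose ≥ 126 mg/dL, or the corresponding HbA1c bands), controls are
normoglycemic. Candidate predictors are (a) nine SNPs previously linked to
glycemic traits (GCKR rs1260326, DGKB rs2191349, GCK rs1799884/rs4607517,
SLC30A8 rs11558471, CDKN2A/B rs10811661, MTNR1B
rs1387153/rs2166706/rs10830963), coded additively as risk-allele dosage
0/1/2; (b) three oxidative-stress biomarkers — malondialdehyde (MDA,
nmol/mL), oxidized LDL (U/L) and 8-epi-prostaglandin F2α (pg/mg creatinine);
and (c) clinical covariates, principally age, sex and BMI.

## Association screening

Each SNP is tested with a per-allele logistic regression of case status on
dosage, with and without adjustment for age, sex and BMI. Fitting is
maximum likelihood via IRLS (statsmodels GLM/Binomial; convergence at
deviance change < 1e-8, ≤ 100 iterations). Inference is Wald: p from
β̂/SE, 95% CI = exp(β̂ ± 1.96·SE); likelihood-ratio p-values are available
behind a flag. Quasi-complete separation is detected (a non-intercept
|β̂| > 15, or statsmodels' own separation signal) and raised as an explicit
`SeparationError` rather than silently diverging. The intercept is exempt
from that check because it legitimately grows large with uncentred
covariates such as BMI.

Allele-level tests reconstruct the 2×2 allele table from the group
risk-allele frequencies (2n chromosomes per group, counts rounded to the
nearest integer): OR = cross-product ratio, Woolf log-scale 95% CI, Pearson
chi-square p. Note the allele-table OR and the per-allele logistic OR are
different estimands; at the shipped panel's frequencies they differ by
well under 1%, but the reference table's genotype-level regression value for
rs10811661 (1.282) differs visibly from the allele-table value (1.267) —
a model difference, not an error.

SNP selection for the risk score follows two filters on the adjusted
p-values: nominal (p < 0.05) and Bonferroni (p < 0.05/9 ≈ 0.006; the
divisor is the full panel size, not the selected-set size). The Bonferroni
set is by construction nested in the nominal set; on the shipped reference
p-values the filters pass six and five SNPs respectively.

## Genetic risk score

GRS_i = Σ_k β̂_k g_ik over the selected SNPs. Weights default to per-SNP
covariate-adjusted fits (one logistic model per SNP, weight = that SNP's
dosage coefficient); a joint-fit option exists (`joint=True`). Per-SNP
fitting was chosen as the default because the score is described as a
per-variant effect summary; with essentially unlinked SNPs the two options
agree closely. Whether the original weights were adjusted or unadjusted is
not documented; adjusted is the default here to match the emphasis on
covariate-adjusted effects.

## Oxidative stress score

Each biomarker is categorized into tertiles, scored T1 = 0, T2 = 1, T3 = 2.
Cutpoints are either derived from the data — the 1/3 and 2/3 sample
quantiles with linear interpolation between closest order statistics,
h = (n−1)p + 1 — or fixed to the published values (ox-LDL 36.34 / 51.76 U/L,
MDA 7.44 / 9.41 nmol/mL, 8-epi-PGF2α 1117.49 / 1615.60 pg/mg creatinine),
which ship with the package. Tertile intervals are upper-inclusive:
(−∞, c1], (c1, c2], (c2, ∞) — "lowest through c1" read as including c1; a
value exactly on c1 scores 0. Whether the original cutpoints were computed
on all subjects or controls only is not documented; data-derived cutoffs
here use whatever sample is passed to `fit`.

OSS_i = Σ_j β̂_j t_ij with weights from one joint logistic fit of case
status on the three tertile scores (no covariates by default — the
weighting model is the score's own definition; adjustment is available via
`covariate_cols`). `unweighted=True` gives the plain tertile sum.

## ROC analysis and model comparison

ROC curves are built on the distinct observed score values (ties grouped
into a single vertex; ±∞ sentinels), AUC by the trapezoidal rule. This is
algebraically identical to the Mann–Whitney statistic
P(case score > control score) + ½·P(tie), which the package computes
independently from midranks as a cross-check; the identity is fuzz-tested
to 1e-12 including heavily tied data.

The optimal cutoff maximizes Youden's J = sensitivity + specificity − 1
(the standard reading of "optimal"; a closest-to-(0,1) criterion is
available). Candidate cutoffs are midpoints between consecutive distinct
scores plus the two infinite rules, so reported cutoffs are data-dependent
values in the score's own units; ties in J break toward the lowest cutoff.

Six candidate models are compared: BMI, OSS, GRS alone, BMI+OSS, OSS+GRS,
BMI+OSS+GRS. Single-feature models rank subjects by the raw feature (AUC is
invariant to monotone transforms, so no fit is needed); multi-feature models
rank by the in-sample predicted probability of a logistic fit — the only
combiner consistent with the logistic framework of the rest of the
analysis. All AUCs are apparent (in-sample); no optimism correction is
applied, matching the design being modelled. A forward-stepwise logistic
screen (entry p < 0.05, removal p > 0.10) is provided for covariate
selection, with glucose-pathway variables (fasting glucose, insulin,
HOMA-IR, HbA1c) intended to be passed as exclusions since they define the
phenotype itself.

## Synthetic cohort generator

The generator's defaults are the published group-level parameters: 549
cases / 1036 controls; per-group risk-allele frequencies of the nine-SNP
panel; biomarker group means ± SE (MDA 8.28 ± 0.07 control / 10.4 ± 0.23
case, ox-LDL 45.2 ± 0.63 / 51.0 ± 0.87, 8-epi-PGF2α 1559.7 ± 21.3 /
1597.3 ± 35.1); age 47.0 / 52.9 y, BMI 23.8 / 24.7 kg/m², male proportion
0.354 / 0.495 (sex coded 0 = female, 1 = male).

* **Genotypes** are Binomial(2, RAF) within each outcome group — i.e.
  Hardy–Weinberg equilibrium within group at the group's frequency. This is
  a retrospective-sampling approximation: real case-control genotypes need
  not be in within-group HWE, and the approximation shifts the implied
  per-allele OR by well under 1% at these frequencies. SNPs are simulated
  independently; the three MTNR1B SNPs are in strong linkage
  disequilibrium in reality, which the generator does not emulate.
* **Biomarkers** are log-normal per group (the standard positive,
  right-skewed form for these assays), with (μ, σ) solved by method of
  moments from the target arithmetic mean and SD; SD is reconstructed from
  the printed SE as SE·√n of the configured group, so configs at the
  published group sizes reproduce the published SDs exactly. A zero SE
  yields the degenerate constant. Within-group biomarkers are independent
  by default — the source tables give no correlations — and an optional
  Gaussian copula imposes a rank-correlation matrix when one is supplied.
* **Covariates**: age and BMI normal per group, sex Bernoulli per group.
* **Reproducibility**: one master seed spawns named substreams (genotypes,
  biomarkers, covariates), so adding a sampler never perturbs the others,
  and identical configs give bitwise-identical cohorts.

What passing tests on this generator do **not** show: recovery of the
original cohort's multivariable results (GRS OR 1.946, OSS OR 2.270, AUROC
0.693 → 0.705). Those depend on the joint individual-level distribution —
between-biomarker and gene–biomarker dependence, LD, covariate–outcome
structure — which group-level summaries cannot pin down and which the
original data (not deposited) would be needed to reproduce. The pipeline
therefore validates itself on printed self-contained quantities (allele-table
ORs, filter counts, cutpoint arithmetic) and on closed-form and simulation
oracles at known effect sizes.

## Numerical and testing choices

* Pooled-variance t-test as the two-group default (Welch behind a flag);
  the no-covariate ANCOVA route reproduces it exactly (F = t²,
  agreement to 1e-10).
* Logistic oracle identity: on a single binary predictor the fitted β
  equals the 2×2 log cross-product ratio; fuzz-tested to 1e-8 over random
  tables with all cells ≥ 1.
* Wald 95% CI calibration: coverage of known generating effects is
  95% ± 2% over 1000 replicates at n = 2000, for both a per-SNP dosage β
  and jointly fitted tertile weights.
* Monte-Carlo test sizes: convergence checks use 20 000–100 000 subjects
  per group with 3-MC-SE tolerances; null-calibration checks use 1000
  replicates with a ±0.02 band around α = 0.05. The acceptance script
  refits the reference allele ORs at 100 000 subjects per group, where the
  analytic SE of the log OR is ≈ 0.007.
* Report tables print floats at 6 significant digits; manifests carry the
  seed and a config hash, and deliberately no timestamps, so bundles are
  byte-comparable.

## Known limitations

* No LD between SNPs; no gene–environment or gene–biomarker dependence in
  the generator unless configured through the copula.
* The GRS/OSS weighting is in-sample; no shrinkage, cross-validation or
  external-validation machinery is provided.
* Allele tables reconstructed from printed frequencies inherit a rounding
  error of a few parts per thousand in the OR.
* Firth/exact logistic regression is out of scope; separation is an error,
  not a fallback.
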