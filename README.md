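# dtameta

Diagnostic test accuracy (DTA) meta-analysis of expression biomarkers.

Screening a gene-expression biomarker across several case/control cohorts
poses two problems at once: turning continuous expression into a diagnostic
call within each cohort, and combining the resulting per-cohort accuracies
into one defensible summary. `dtameta` implements the classical pipeline for
both steps:

1. **Per-cohort classification.** A univariate logistic regression of
   case/control status on (log2, quantile-normalized) expression,
   P(case) = expit(β₀ + β₁·x), classifies every sample at the 0.5
   probability cutoff and yields one 2×2 confusion table (TP/FP/FN/TN) per
   cohort.
2. **Pooling.** Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) pool as
   aggregate proportions (Σ numerators / Σ denominators). The positive and
   negative likelihood ratios and the diagnostic odds ratio
   DOR = (TP·TN)/(FP·FN) pool on the natural-log scale with
   DerSimonian–Laird random effects,
   τ² = max(0, (Q − df)/(Σw − Σw²/Σw)); heterogeneity is reported as
   Cochran's Q and I² = max(0, (Q − df)/Q)·100.
3. **Summary ROC.** The Moses–Littenberg regression D = a + b·S, with
   D = logit(TPR) − logit(FPR) = ln DOR and S = logit(TPR) + logit(FPR),
   inverts to the summary curve
   TPR(FPR) = expit(a/(1−b) + logit(FPR)·(1+b)/(1−b)), integrated by
   trapezoid for the AUC; Q\* = expit(a/2) is the sensitivity = specificity
   point. When |b| ≥ 1 the asymmetric curve is improper and the symmetric
   (slope-0, constant-DOR) curve with the fitted intercept is used, as in
   classical DTA software.

Around the core sit a multi-study synthetic cohort generator (Gaussian log2
intensities, a marker gene down-shifted in cases, per-study baselines, noise
genes), expression/phenotype TSV I/O with quantile normalization, a
multi-biomarker comparison pipeline, and Pearson similar-gene ranking.

It ships with a worked data set: the five published 2×2 tables for
chromogranin-A (CHGA) expression as an early colon-cancer biomarker,
obtained by logistic classification of four GEO microarray cohorts
(GSE44076 with two control arms, GSE74602, GSE10972, GSE23878).

## Worked example

```python
from dtameta import (chga_colon_tables, study_indices, pool_proportion,
                     pool_log_ratio, fit_moses, auc, q_star)

tables = chga_colon_tables()
indices = [study_indices(t) for t in tables]

sens = pool_proportion(tables, "sens")
dor = pool_log_ratio(indices, "dor", model="random")
sroc = fit_moses(indices, weighted=True)
print(f"sens {sens.estimate:.2f}  I2 {sens.i2:.1f}%")
print(f"DOR {dor.estimate:.2f} ({dor.ci_low:.2f}-{dor.ci_high:.2f})")
print(f"AUC {auc(sroc):.4f}  Q* {q_star(sroc):.4f}")
```

prints

```
sens 0.89  I2 25.2%
DOR 57.25 (14.88-220.35)
AUC 0.9361  Q* 0.8725
```

— a pooled sensitivity of 0.89 with modest heterogeneity, a random-effects
diagnostic odds ratio near 57 (cases have ~57-fold higher odds of a positive
call), and a summary ROC area of ~0.94: a strongly discriminating marker.
The same stages are scriptable from the shell (`dtameta meta tables.csv`,
`dtameta sroc tables.csv --weighted`); `examples/` holds one short narrative
script per capability, including simulation and biomarker comparison.

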