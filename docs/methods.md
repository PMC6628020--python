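# Methods

## Model and procedure

`dtameta` treats a continuous expression biomarker as a diagnostic test by a
two-stage procedure.

**Stage 1 — classification.** Within each cohort, case/control status is
regressed on a single gene's expression by maximum-likelihood logistic
regression (IRLS via `statsmodels` GLM with a binomial family, iteration cap
50). Every sample is then classified "case" iff its fitted probability is
≥ 0.5 (ties to "case"), on the same samples the model was fitted on
(resubstitution). This mirrors designs where every sample of every retained
cohort enters the published 2×2 table; it also means per-cohort accuracies
carry a small optimistic bias of order 1/n (see *Limitations*). Complete
separation is not an error: the coefficients diverge, the fit is flagged
non-converged, but the fitted probabilities pin to 0/1 and the confusion
table — the only downstream quantity — is invariant to the divergence.
A constant covariate yields β₁ = 0 and probability equal to prevalence.
The 0.5 cutoff is the convention that turns a logistic fit into a
classifier; a different threshold (e.g. prevalence) can be passed
explicitly.

**Stage 2 — pooling.** Per-study indices come from the 2×2 counts, with a
+0.5 continuity correction on all four cells of any table containing a zero
(ratio indices only). Delta-method variances on the log scale:
var(ln DOR) = 1/TP + 1/FP + 1/FN + 1/TN,
var(ln PLR) = 1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN), and symmetrically for
NLR. Sensitivity and specificity pool as aggregate proportions
(Σnum/Σden over raw counts) with a binomial normal-approximation CI — the
convention of classical DTA meta-analysis software, and the only rule
consistent with reporting both pooled proportions at two decimals from
unbalanced cohorts (inverse-variance logit pooling gives visibly different
values). PLR/NLR/DOR pool on the natural-log scale; the random-effects model
uses the DerSimonian–Laird moment estimator
τ² = max(0, (Q − df)/(Σw − Σw²/Σw)) with weights 1/(vᵢ + τ²). Q and I² are
always computed at the fixed-weight stage. For proportions, Cochran's Q uses
study-specific binomial variances pᵢ(1−pᵢ)/nᵢ around the aggregate estimate;
the variance convention inside Q for proportions is not standardized across
software, which is why the I² of two implementations can differ by several
percentage points on the same table. When one heterogeneity number is
quoted for a biomarker, it is I² on sensitivity, with I² < 50% read as small
heterogeneity.

**Stage 3 — summary ROC.** The Moses–Littenberg regression D = a + b·S
(D = ln DOR, S = logit(TPR) + logit(FPR)) is fitted by least squares,
unweighted by default with an inverse-variance (1/var ln DOR) option. The
curve TPR(FPR) = expit(a/(1−b) + logit(FPR)(1+b)/(1−b)) is integrated by
trapezoid on a uniform FPR grid (step 1e−4, endpoints by their limits;
halving the step moves the AUC by < 1e−6). Q* = expit(a/2) in closed form.
A fitted |b| ≥ 1 makes the asymmetric curve non-monotone; the model is then
flagged degenerate and TPR/AUC are evaluated on the symmetric (b = 0)
curve with the fitted intercept — the reporting behaviour of classical DTA
software, and the regime in which the bundled CHGA tables actually fall
(b ≈ −1.3 under both weightings; the weighted fit reproduces the published
AUC/Q* almost exactly, so the weighted variant is what the reproduction
script reports, with the unweighted one logged alongside). A
restricted-range AUC over the observed FPR interval is available behind a
flag; the headline number integrates over (0, 1). Logits of exact 0/1 are
clamped at ±36 with a warning, though continuity correction upstream makes
this unreachable in normal use.

## Preprocessing

Expression matrices are genes × samples, log2 scale. If a matrix maximum
exceeds 100 the data are taken to be linear-scale and log2(x+1) is applied
(the threshold and a force flag are exposed; the transform decision is
logged per study). Quantile normalization forces every sample onto the mean
order-statistic distribution; ties within a sample receive the mean of the
rank-mean values over the tied ranks (the `normalizeQuantiles` convention).
With ties present, exact idempotence and identical sorted columns hold only
approximately — continuous intensities make ties measure-zero in practice.
Normalization is per-study: cohorts enter the meta-analysis as independent
units, so cross-study normalization would couple what the pooling model
assumes independent.

## Synthetic cohorts

The generator emulates multi-study microarray screening data:

| parameter | default | meaning |
|---|---|---|
| `baseline_mean` | 8.0 | log2-intensity grand mean, typical of array data |
| `baseline_sd` | 1.0 | within-group per-gene SD (log2 units) |
| `marker_shift` | −1.5 | case-minus-control marker mean shift; negative = down in disease; −1.5·SD separates well while leaving nonzero error rates |
| `n_noise_genes` | 50 | genes identically distributed in both groups |
| `study_offset_sd` | 0.5 | SD of the per-study baseline offset (platform/lab location differences) |

All intensities are Gaussian on the log2 scale — the simplest model
consistent with analyzing microarray data after log transformation; the
distribution family is an assumption of this package, not something the
classification stage requires. Per-study offsets force classification to be
per-cohort rather than on pooled samples. One global seed fans out to
per-study child seeds by fixed arithmetic (seed·1000 + index), so adding a
cohort never perturbs earlier ones and equal specs give bit-identical
matrices. `generate_paperlike_set` produces five cohorts with case/control
counts 98/50, 97/98, 31/29, 24/24, 35/24 — the layout of the bundled CHGA
analysis, where the first microarray series contributes two control arms.

What the generator does *not* model: probe-level effects, batch/array
artifacts, missing values, heavy-tailed intensities, or correlated gene
blocks (noise genes are independent). Passing tests on synthetic data
therefore demonstrate the statistical machinery — type-I behaviour, operating
-point recovery, ranking power — not robustness to real-array pathology.

## Test design choices

* The type-I sanity check (null marker, pooled DOR within [1/2.5, 2.5] in
  each of 100 replicates) runs on five cohorts of 100 cases/100 controls.
  Resubstitution keeps the null pooled DOR slightly above 1 (geometric mean
  ≈ 1.2 at this size); at the smallest realistic cohort sizes (24/24) the
  optimism widens the null spread enough that occasional replicates leave
  the band — a property of resubstitution classification, not of pooling.
* The operating-point check compares observed per-study sensitivity and
  specificity against an oracle that numerically integrates the true
  class-conditional Gaussians at the classifier's fitted cut, with 2000
  samples per arm so the O(1/n) resubstitution optimism is negligible
  against the O(1/√n) binomial standard error.
* DerSimonian–Laird pooling is cross-checked in the tests against frozen
  reference values from an independent R `metafor` run
  (`rma(yi, vi, method="DL")`) on the bundled tables.

## Limitations

* The Moses–Littenberg model is known to bias the SROC when threshold and
  accuracy correlate; hierarchical alternatives (bivariate Reitsma, HSROC)
  are out of scope here, as is meta-regression and publication-bias testing.
* Resubstitution accuracy is optimistic by construction; no cross-validated
  operating points are produced.
* Aggregate-proportion pooling ignores between-study weighting for
  sensitivity/specificity; it is reported for fidelity to the classical
  convention, with heterogeneity statistics alongside.
* Multi-cohort similar-gene ranking averages per-cohort Pearson r without
  weighting — an extension of the usual single-cohort computation, flagged
  as such in the API docs.
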